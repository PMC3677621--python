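"""Equilibria of the reduced system: location, census and local stability.

The disease-free equilibrium is ``P0 = (b/(sigma_a + b), 0, 0)``.  Interior
(endemic) equilibria are found by reducing the three equilibrium relations to
a single scalar equation in the infective proportion i.  Setting the reduced
right-hand sides to zero gives, in turn,

    e(i) = i * (alpha + gamma + b - alpha*i) / epsilon          (i-equation)
    s(i) = e(i) * (b + epsilon - alpha*i)
           / [beta*(1-sigma_a) * (i + q*e(i))]                  (e-equation)

and substituting both into the s-equation leaves the scalar residual

    h(i) = e(i)*(b + epsilon - alpha*i) + s(i)*(sigma_a + b - alpha*i) - b,

whose zeros in (0, 1) are exactly the endemic equilibria.  Clearing
denominators turns ``h`` into the difference of a quartic ``f`` and a linear
function ``g``::

    f(i) = f1(i) * (b + epsilon - alpha*i) * (alpha + gamma + b - alpha*i)
    f1(i) = -(alpha*q*beta*(1-sigma_a)/epsilon) * i**2
            + (beta*(1-sigma_a)*(epsilon + q*(alpha+gamma+b))/epsilon - alpha) * i
            + (sigma_a + b)
    g(i) = b*beta*(1-sigma_a) * [q*(alpha+gamma+b) + epsilon - alpha*q*i]

with ``f(i) = g(i)`` at every equilibrium.  At ``i = 0`` the ratio
``g(0)/f(0)`` is exactly the basic reproduction number R0, which is why the
endemic branch enters the unit interval precisely when R0 crosses 1 (see
:mod:`seirvax.thresholds`).

Root-finding scans a uniform grid for sign changes of ``h`` and refines each
bracket with Brent's method; every candidate is validated against the full
vector field, which discards sign changes caused by the pole of ``s(i)`` at
``i + q*e(i) = 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .exceptions import AmbiguousRootsError, DegenerateParametersError, DomainError
from .model import Parameters, ProportionState, jacobian_reduced, rhs_reduced

__all__ = [
    "EquilibriumRecord",
    "EndemicDiagnostics",
    "disease_free_equilibrium",
    "endemic_scalar_residual",
    "endemic_curves",
    "endemic_diagnostics",
    "solve_endemic",
    "find_all_equilibria",
    "classify_stability",
]

logger = logging.getLogger(__name__)

#: tolerance on the real part of an eigenvalue below which it counts as zero
STABILITY_TOL = 1e-9
#: maximum admissible max-norm of the vector field at a reported equilibrium
RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class EquilibriumRecord:
    """An equilibrium, its spectrum and its local stability classification."""

    location: ProportionState
    kind: str  # "disease-free" | "endemic" | "other"
    eigenvalues: Optional[Tuple[complex, complex, complex]] = None
    max_real_part: Optional[float] = None
    label: Optional[str] = None  # "stable" | "unstable" | "marginal"
    feasible: bool = True
    residual: float = 0.0


@dataclass(frozen=True)
class EndemicDiagnostics:
    """The scalar endemic construction: curve coefficients and located roots."""

    i_roots: Tuple[float, ...]
    f1_coefficients: Tuple[float, float, float]  # (c2, c1, c0), f1(i) = c2 i^2 + c1 i + c0
    g_slope: float
    g_intercept: float
    interval: Tuple[float, float]


def _e_of_i(i, p: Parameters):
    return i * (p.alpha + p.gamma + p.b - p.alpha * i) / p.epsilon


def _s_of_i(i, p: Parameters):
    e = _e_of_i(i, p)
    return e * (p.b + p.epsilon - p.alpha * i) / (p.beta_eff * (i + p.q * e))


def _residual(i, p: Parameters):
    """Scalar equilibrium residual; vectorised over ``i``."""
    e = _e_of_i(i, p)
    s = _s_of_i(i, p)
    return e * (p.b + p.epsilon - p.alpha * i) + s * (p.sigma_a + p.b - p.alpha * i) - p.b


def endemic_scalar_residual(i: float, params: Parameters) -> float:
    """Residual of the scalar endemic equation at an infective proportion i in (0, 1).

    Zero exactly when ``(s(i), e(i), i)`` is an equilibrium of the reduced
    system.  For exploration outside the unit interval use
    :func:`find_all_equilibria`.
    """
    i = float(i)
    if not 0.0 < i < 1.0:
        raise DomainError(f"endemic_scalar_residual is defined on (0, 1); got i = {i!r}")
    if params.epsilon <= 0 or params.beta_eff == 0.0:
        raise DegenerateParametersError("epsilon > 0 and beta*(1 - sigma_a) != 0 are required")
    return float(_residual(i, params))


def endemic_curves(params: Parameters) -> Tuple[Tuple[float, float, float], float, float]:
    """Coefficients of the denominator-cleared curves f and g.

    Returns ``((c2, c1, c0), g_slope, g_intercept)`` with
    ``f1(i) = c2 i^2 + c1 i + c0`` and ``g(i) = g_intercept + g_slope * i``.
    """
    p = params
    if p.epsilon <= 0:
        raise DegenerateParametersError("epsilon must be > 0")
    be = p.beta_eff
    agb = p.alpha + p.gamma + p.b
    c2 = -p.alpha * p.q * be / p.epsilon
    c1 = be * (p.epsilon + p.q * agb) / p.epsilon - p.alpha
    c0 = p.sigma_a + p.b
    g_slope = -p.b * be * p.alpha * p.q
    g_intercept = p.b * be * (p.q * agb + p.epsilon)
    return (c2, c1, c0), g_slope, g_intercept


def _record_from_i(i: float, params: Parameters, classify: bool = True) -> EquilibriumRecord:
    loc = ProportionState(float(_s_of_i(i, params)), float(_e_of_i(i, params)), float(i))
    res = float(np.abs(rhs_reduced(loc, params)).max())
    feas = loc.feasible
    kind = "endemic" if (0.0 < i < 1.0 and feas) else "other"
    rec = EquilibriumRecord(location=loc, kind=kind, feasible=feas, residual=res)
    return classify_stability(rec, params) if classify else rec


def disease_free_equilibrium(params: Parameters) -> EquilibriumRecord:
    """The disease-free equilibrium ``(b/(sigma_a + b), 0, 0)``, classified."""
    denom = params.sigma_a + params.b
    if denom <= 0:
        raise DegenerateParametersError("sigma_a + b must be > 0")
    loc = ProportionState(params.b / denom, 0.0, 0.0)
    res = float(np.abs(rhs_reduced(loc, params)).max())
    rec = EquilibriumRecord(location=loc, kind="disease-free", feasible=loc.feasible, residual=res)
    return classify_stability(rec, params)


def _scan_roots(
    params: Parameters,
    interval: Tuple[float, float],
    grid_points: int,
) -> List[float]:
    """Sign-change scan + Brent refinement of the scalar residual on ``interval``.

    Candidates whose full-state residual exceeds ``RESIDUAL_TOL`` (pole
    crossings of ``s(i)``) are discarded.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise DomainError("interval bounds must be finite")
    if hi <= lo:
        return []
    # keep strictly away from i = 0, where the disease-free equilibrium lives
    tiny = max(1e-12, 1e-9 * (hi - lo))
    lo = max(lo, tiny)
    grid = np.linspace(lo, hi, grid_points)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        vals = _residual(grid, params)
    ok = np.isfinite(vals)
    roots: List[float] = []
    sgn = np.sign(vals)
    for k in range(len(grid) - 1):
        if not (ok[k] and ok[k + 1]):
            continue
        if sgn[k] == 0.0:
            roots.append(float(grid[k]))
            continue
        if sgn[k] * sgn[k + 1] < 0:
            try:
                r = brentq(lambda x: float(_residual(x, params)), grid[k], grid[k + 1],
                           xtol=1e-14, rtol=8.9e-16, maxiter=200)
            except ValueError:  # pragma: no cover - defensive
                continue
            roots.append(float(r))
    # validate against the full vector field and deduplicate
    out: List[float] = []
    for r in roots:
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            res = np.abs(rhs_reduced([_s_of_i(r, params), _e_of_i(r, params), r], params)).max()
        if not np.isfinite(res) or res > RESIDUAL_TOL:
            logger.debug("discarding spurious sign change at i=%g (residual %g)", r, res)
            continue
        if out and abs(r - out[-1]) < 1e-10 * max(1.0, abs(r)):
            continue
        out.append(r)
    return out


def solve_endemic(params: Parameters, grid_points: int = 10001) -> Optional[EquilibriumRecord]:
    """Locate the feasible endemic equilibrium with i in (0, 1), or ``None`` if absent.

    Only roots whose full state (s, e, i) lies in the simplex T qualify: in
    the below-replacement regime b < alpha the scalar equation can have roots
    in (0, 1) whose back-substituted s exceeds 1, which are biologically
    meaningless (they remain visible through :func:`find_all_equilibria`).
    Raises :class:`AmbiguousRootsError` when several feasible roots are
    found, which violates the uniqueness asserted by the endemic-existence
    theorem and is surfaced rather than hidden (it does occur when b < alpha).
    """
    if params.beta_eff == 0.0 or params.epsilon <= 0:
        return None
    roots = _scan_roots(params, (0.0, 1.0), grid_points)
    records = [_record_from_i(r, params) for r in roots]
    records = [rec for rec in records if rec.location.is_feasible(tol=1e-12)]
    if not records:
        return None
    if len(records) > 1:
        raise AmbiguousRootsError([rec.location.i for rec in records])
    return records[0]


def endemic_diagnostics(
    params: Parameters,
    i_interval: Tuple[float, float] = (0.0, 1.0),
    grid_points: int = 10001,
) -> EndemicDiagnostics:
    """Curve coefficients of the endemic construction plus located roots."""
    f1, g_slope, g_intercept = endemic_curves(params)
    roots = _scan_roots(params, i_interval, grid_points) if params.beta_eff != 0.0 else []
    return EndemicDiagnostics(
        i_roots=tuple(roots),
        f1_coefficients=f1,
        g_slope=g_slope,
        g_intercept=g_intercept,
        interval=(float(i_interval[0]), float(i_interval[1])),
    )


def find_all_equilibria(
    params: Parameters,
    i_interval: Tuple[float, float] = (0.0, 1.0),
    grid_points: int = 20001,
) -> List[EquilibriumRecord]:
    """Census every real equilibrium with i in ``i_interval``, plus the disease-free point.

    Records outside the simplex T carry ``feasible = False``; the list is
    sorted by the i-component.  An empty or degenerate interval returns only
    the disease-free record.
    """
    records = [disease_free_equilibrium(params)]
    if params.beta_eff != 0.0 and params.epsilon > 0:
        for r in _scan_roots(params, i_interval, grid_points):
            records.append(_record_from_i(r, params))
    records.sort(key=lambda rec: rec.location.i)
    return records


def classify_stability(record: EquilibriumRecord, params: Parameters) -> EquilibriumRecord:
    """Fill eigenvalues and the stable/unstable/marginal label of a record.

    The label follows the sign of the largest real part with tolerance
    ``STABILITY_TOL``; "marginal" is an explicit outcome, not a coin flip.
    """
    lam = np.linalg.eigvals(jacobian_reduced(record.location, params))
    mrp = float(lam.real.max())
    if mrp < -STABILITY_TOL:
        label = "stable"
    elif mrp > STABILITY_TOL:
        label = "unstable"
    else:
        label = "marginal"
    return replace(
        record,
        eigenvalues=tuple(complex(v) for v in lam),
        max_real_part=mrp,
        label=label,
    )
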