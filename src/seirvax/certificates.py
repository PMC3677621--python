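"""Global-stability machinery evaluated as numerical diagnostics along trajectories.

Two certificates are implemented.  Neither is a proof: both are finite-horizon
numerical checks of the inequalities that the corresponding analytical
arguments rely on.

Lyapunov (disease-free side)
    The linear function ``L = (alpha + gamma + b) e + beta (1 - sigma_a) i``
    is non-increasing along solutions whenever R01 <= 1 and the transmission
    coefficient dominates disease mortality (``beta (1 - sigma_a) >= alpha``):
    its orbital derivative then satisfies
    ``L' <= e (alpha + gamma + b)(b + epsilon)(R01 - 1)`` on the feasible
    simplex, so LaSalle's invariance principle drives every trajectory to the
    disease-free equilibrium.  Outside that regime the disease-mortality term
    ``alpha e i`` can make L increase transiently (see docs/methods.md).

Lozinskii (endemic side, Li-Muldowney geometric criterion)
    Along an interior trajectory the Lozinskii measure of the weighted second
    additive compound is bounded by ``sup(g1, g2)`` with

        g1 = e'/e - beta (1 - sigma_a)(i + q e) - (sigma_a + b) + 2 alpha i
        g2 = e'/e + 2 alpha i - b - min{sigma_a, epsilon}

    Under the endemic-side conditions (b >= alpha, alpha < min{sigma_a, b,
    epsilon}) the margin ``m = min{sigma_a + b - 2 alpha,
    b + min{sigma_a, epsilon} - 2 alpha}`` is positive and
    ``sup(g1, g2) <= e'/e - m`` pointwise, which makes the time average of the
    measure eventually negative and certifies contraction.  The published
    margin uses ``max`` instead of ``min``; with ``max`` the pointwise bound
    fails whenever the two margins differ, so the ``min`` form gates
    ``bound_satisfied`` and the ``max`` form is reported alongside for
    transparency (``margin_printed``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .exceptions import DomainError, InvalidInputError
from .model import Parameters, ProportionState, rhs_reduced
from .simulate import Trajectory
from .thresholds import check_theorems

__all__ = [
    "CertificateReport",
    "lyapunov_value",
    "lyapunov_derivative",
    "lyapunov_diagnostics",
    "lozinskii_diagnostics",
    "check_global_stability_conditions",
]

#: trajectory samples with e below this are rejected rather than regularized
INTERIOR_E_TOL = 1e-12


@dataclass(frozen=True)
class CertificateReport:
    """Samples of a certificate quantity along a trajectory, plus verdicts.

    For kind "lyapunov", ``values`` holds L(t) and ``monotone_nonincreasing``
    is the verdict.  For kind "lozinskii", ``values`` holds sup(g1, g2)(t),
    ``margin`` the min-form margin m, ``margin_printed`` the published
    max-form, and ``bound_satisfied`` whether sup(g1, g2) <= e'/e - m held at
    every sample (with 1e-9 slack).
    """

    kind: str  # "lyapunov" | "lozinskii"
    times: np.ndarray
    values: np.ndarray
    monotone_nonincreasing: Optional[bool] = None
    bound_satisfied: Optional[bool] = None
    margin: Optional[float] = None
    margin_printed: Optional[float] = None
    g1: Optional[np.ndarray] = None
    g2: Optional[np.ndarray] = None
    e_log_derivative: Optional[np.ndarray] = None
    time_average_satisfied: Optional[bool] = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if len(t) == 0:
            raise InvalidInputError("certificate report needs at least one sample")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("sample times must be strictly increasing")

    @property
    def samples(self) -> Tuple[Tuple[float, float], ...]:
        return tuple(zip(self.times.tolist(), self.values.tolist()))


def lyapunov_value(state: ProportionState | Sequence[float], params: Parameters) -> float:
    """L = (alpha + gamma + b) e + beta (1 - sigma_a) i."""
    if isinstance(state, ProportionState):
        e, i = state.e, state.i
    else:
        _, e, i = np.asarray(state, dtype=float)
    return (params.alpha + params.gamma + params.b) * e + params.beta_eff * i


def lyapunov_derivative(state: ProportionState | Sequence[float], params: Parameters) -> float:
    """Orbital derivative of L, by the chain rule through the vector field.

    On the feasible simplex T and provided ``beta*(1 - sigma_a) >= alpha``,
    it satisfies ``L' <= e (alpha + gamma + b)(b + epsilon)(R01 - 1)``; see
    docs/methods.md for why the disease-mortality term makes that proviso
    necessary.
    """
    ds = rhs_reduced(state, params)
    return float((params.alpha + params.gamma + params.b) * ds[1] + params.beta_eff * ds[2])


def lyapunov_diagnostics(traj: Trajectory, params: Parameters, slack: float = 1e-9) -> CertificateReport:
    """Evaluate L along a trajectory and check monotone non-increase."""
    if traj.kind != "reduced":
        raise InvalidInputError("lyapunov diagnostics expect a reduced-system trajectory")
    agb = params.alpha + params.gamma + params.b
    L = agb * traj.e + params.beta_eff * traj.i
    mono = bool(np.all(np.diff(L) <= slack))
    return CertificateReport(kind="lyapunov", times=traj.times, values=L, monotone_nonincreasing=mono)


def lozinskii_diagnostics(traj: Trajectory, params: Parameters, slack: float = 1e-9) -> CertificateReport:
    """g1, g2 and the Lozinskii-measure bound along an interior trajectory.

    Raises :class:`DomainError` if the trajectory touches the boundary
    (e <= 1e-12 or i <= 0 at any sample): the certificate is undefined there.
    """
    if traj.kind != "reduced":
        raise InvalidInputError("lozinskii diagnostics expect a reduced-system trajectory")
    p = params
    s, e, i = traj.s, traj.e, traj.i
    if np.any(e <= INTERIOR_E_TOL) or np.any(i <= 0.0):
        raise DomainError("trajectory must stay in the interior of T (e > 1e-12, i > 0)")
    inc = p.beta_eff * s * (i + p.q * e)
    e_prime = inc - (p.b + p.epsilon) * e + p.alpha * e * i
    eoe = e_prime / e
    g1 = eoe - p.beta_eff * (i + p.q * e) - (p.sigma_a + p.b) + 2.0 * p.alpha * i
    g2 = eoe + 2.0 * p.alpha * i - p.b - min(p.sigma_a, p.epsilon)
    m1 = p.sigma_a + p.b - 2.0 * p.alpha
    m2 = p.b + min(p.sigma_a, p.epsilon) - 2.0 * p.alpha
    m = min(m1, m2)
    m_printed = max(p.sigma_a + p.b - 2.0 * p.alpha, p.b + p.epsilon - 2.0 * p.alpha)
    sup = np.maximum(g1, g2)
    bound = bool(np.all(sup <= eoe - m + slack))
    # finite-horizon echo of the asymptotic time-average argument:
    # (1/t) int_0^t sup(g1,g2) ds + m  <=  (1/t) int_0^t e'/e ds  (= (log e(t) - log e(0))/t)
    # Both integrals use the same trapezoid rule so that the pointwise bound
    # implies the discrete inequality regardless of the sampling density.
    ta_ok: Optional[bool] = None
    if len(traj) > 2:
        def _cum(v):
            return np.concatenate(([0.0], np.cumsum(np.diff(traj.times) * 0.5 * (v[1:] + v[:-1]))))

        t_rel = traj.times - traj.times[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            avg = _cum(sup)[1:] / t_rel[1:]
            rhs = _cum(eoe)[1:] / t_rel[1:]
        ta_ok = bool(np.all(avg + m <= rhs + 1e-6))
    return CertificateReport(
        kind="lozinskii",
        times=traj.times,
        values=sup,
        bound_satisfied=bound,
        margin=float(m),
        margin_printed=float(m_printed),
        g1=g1,
        g2=g2,
        e_log_derivative=eoe,
        time_average_satisfied=ta_ok,
    )


def check_global_stability_conditions(params: Parameters) -> Tuple[bool, Dict[str, bool]]:
    """Endemic-side global-stability hypothesis set, itemized.

    The conjunction of b >= alpha, Delta > 1, R01 > 1 and
    alpha < min{sigma_a, b, epsilon}, with Delta taken as ``delta_ratio``.
    """
    report = check_theorems(params)
    return report.theorem4_applies, dict(report.theorem4_conditions)
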