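"""Reproduction numbers, the endemic-existence threshold and theorem hypothesis checks.

Two reproduction numbers govern the model:

    R0  = b * beta * (1 - sigma_a) * (q*(alpha + gamma + b) + epsilon)
          / [(b + epsilon) * (alpha + b + gamma) * (sigma_a + b)]

    R01 = beta * (1 - sigma_a) * (q*(alpha + gamma + b) + epsilon)
          / [(b + epsilon) * (alpha + b + gamma)]

so that ``R0 = R01 * b / (sigma_a + b)`` identically and ``R01 >= R0`` with
equality iff vaccination is absent.  ``R0 < 1`` gives local stability of the
disease-free equilibrium; ``R01 <= 1`` upgrades it to global stability via a
linear Lyapunov function (:mod:`seirvax.certificates`).

The endemic-existence quantity Delta is exposed in three readings because the
published formula is internally inconsistent (see docs/methods.md):

``delta_printed``
    the closed-form expression as printed, under the reading in which its
    second factor is ``gamma/b + 1``.  Diagnostic only.
``delta_ratio``
    the authoritative threshold: the ratio ``g(0)/f(0)`` of the two
    denominator-cleared equilibrium curves of :mod:`seirvax.equilibria` at
    ``i = 0``.  Algebraically this equals R0, and (for b >= alpha) an endemic
    equilibrium exists in (0, 1) precisely when it exceeds 1.
``delta_endpoint``
    the endpoint ratio ``f(1)/g(1)``.  Diagnostic only: whenever b >= alpha
    one can show f(1)/g(1) >= (gamma + b)/b > 1, so it cannot discriminate
    existence.

All theorem hypothesis sets are evaluated with strict inequalities exactly as
stated; boundary cases report the theorem as not applying.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, NamedTuple

from .equilibria import endemic_curves
from .exceptions import DegenerateParametersError
from .model import Parameters

__all__ = ["ThresholdReport", "compute_R0", "compute_R01", "compute_delta", "check_theorems"]


class DeltaPair(NamedTuple):
    printed: float
    ratio: float


@dataclass(frozen=True)
class ThresholdReport:
    """Thresholds plus itemized hypothesis sets of the four stability theorems."""

    R0: float
    R01: float
    delta_printed: float
    delta_ratio: float
    delta_endpoint: float
    theorem1_applies: bool
    theorem2_applies: bool
    theorem3_applies: bool
    theorem4_applies: bool
    theorem1_conditions: Dict[str, bool] = field(default_factory=dict)
    theorem2_conditions: Dict[str, bool] = field(default_factory=dict)
    theorem3_conditions: Dict[str, bool] = field(default_factory=dict)
    theorem4_conditions: Dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "R0": self.R0,
            "R01": self.R01,
            "delta_printed": self.delta_printed,
            "delta_ratio": self.delta_ratio,
            "delta_endpoint": self.delta_endpoint,
            "theorem1": {"applies": self.theorem1_applies, "conditions": dict(self.theorem1_conditions)},
            "theorem2": {"applies": self.theorem2_applies, "conditions": dict(self.theorem2_conditions)},
            "theorem3": {"applies": self.theorem3_applies, "conditions": dict(self.theorem3_conditions)},
            "theorem4": {"applies": self.theorem4_applies, "conditions": dict(self.theorem4_conditions)},
        }


def compute_R01(params: Parameters) -> float:
    """Vaccination-free reproduction number R01 (global disease-free threshold)."""
    p = params
    denom = (p.b + p.epsilon) * (p.alpha + p.b + p.gamma)
    if denom <= 0:
        raise DegenerateParametersError("(b + epsilon)(alpha + b + gamma) must be > 0")
    return p.beta_eff * (p.q * (p.alpha + p.gamma + p.b) + p.epsilon) / denom


def compute_R0(params: Parameters) -> float:
    """Basic reproduction number R0 (local disease-free threshold)."""
    p = params
    denom = p.sigma_a + p.b
    if denom <= 0:
        raise DegenerateParametersError("sigma_a + b must be > 0")
    return compute_R01(p) * p.b / denom


def compute_delta(params: Parameters) -> DeltaPair:
    """The endemic-existence quantity Delta as ``(printed, ratio)``.

    ``ratio`` is authoritative (see module docstring); ``printed`` evaluates
    the published closed form under the ``gamma/b + 1`` reading and is kept
    as a diagnostic.
    """
    p = params
    if p.epsilon <= 0 or p.b <= 0:
        raise DegenerateParametersError("epsilon > 0 and b > 0 are required")
    be_q = p.beta_eff * (p.q * p.b + p.q * p.gamma + p.epsilon)
    if be_q <= 0:
        raise DegenerateParametersError("beta*(1 - sigma_a)*(q*b + q*gamma + epsilon) must be > 0")
    printed = (
        (p.b + p.epsilon - p.alpha)
        * (p.gamma / p.b + 1.0)
        * (1.0 / p.epsilon - (p.sigma_a + p.b - p.alpha) / be_q)
    )
    (c2, c1, c0), g_slope, g_intercept = endemic_curves(p)
    f0 = c0 * (p.b + p.epsilon) * (p.alpha + p.gamma + p.b)
    ratio = g_intercept / f0
    return DeltaPair(printed=printed, ratio=ratio)


def _delta_endpoint(params: Parameters) -> float:
    p = params
    (c2, c1, c0), g_slope, g_intercept = endemic_curves(p)
    f1 = ((c2 + c1) + c0) * (p.b + p.epsilon - p.alpha) * (p.gamma + p.b)
    g1 = g_intercept + g_slope
    if g1 == 0:
        raise DegenerateParametersError("g(1) vanishes for this parameter set")
    return f1 / g1


def check_theorems(params: Parameters) -> ThresholdReport:
    """Evaluate the hypothesis sets of the four stability theorems.

    * Theorem 1 (local stability of the disease-free point): R0 < 1.
    * Theorem 2 (global stability of the disease-free point): R01 <= 1.
    * Theorem 3 (existence/uniqueness of the endemic point): b >= alpha and Delta > 1.
    * Theorem 4 (global stability of the endemic point): b >= alpha, Delta > 1,
      R01 > 1 and alpha < min{sigma_a, b, epsilon}.

    Delta is taken as ``delta_ratio``.
    """
    p = params
    r0 = compute_R0(p)
    r01 = compute_R01(p)
    try:
        delta = compute_delta(p)
        endpoint = _delta_endpoint(p)
    except DegenerateParametersError:
        # no transmission (or epsilon = 0): the endemic branch is empty and
        # the printed closed form is undefined; the existence ratio is 0
        (c2, c1, c0), _, g_intercept = endemic_curves(p)
        f0 = c0 * (p.b + p.epsilon) * (p.alpha + p.gamma + p.b)
        delta = DeltaPair(printed=float("nan"), ratio=g_intercept / f0 if f0 > 0 else float("nan"))
        endpoint = float("nan")
    t1 = {"R0 < 1": r0 < 1.0}
    t2 = {"R01 <= 1": r01 <= 1.0}
    t3 = {"b >= alpha": p.b >= p.alpha, "delta > 1": delta.ratio > 1.0}
    t4 = {
        "b >= alpha": p.b >= p.alpha,
        "delta > 1": delta.ratio > 1.0,
        "R01 > 1": r01 > 1.0,
        "alpha < min(sigma_a, b, epsilon)": p.alpha < min(p.sigma_a, p.b, p.epsilon),
    }
    return ThresholdReport(
        R0=r0,
        R01=r01,
        delta_printed=delta.printed,
        delta_ratio=delta.ratio,
        delta_endpoint=endpoint,
        theorem1_applies=all(t1.values()),
        theorem2_applies=all(t2.values()),
        theorem3_applies=all(t3.values()),
        theorem4_applies=all(t4.values()),
        theorem1_conditions=t1,
        theorem2_conditions=t2,
        theorem3_conditions=t3,
        theorem4_conditions=t4,
    )
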