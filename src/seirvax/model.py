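"""Core calculus of the SEIR model with vaccination and an infectious latent class.

The population is split into susceptible (S), exposed/latent (E), infective (I)
and recovered (R) classes.  Susceptibles are vaccinated at per-capita rate ``a``
with efficacy ``sigma``; only the fraction ``sigma`` of vaccinated susceptibles
acquires immunity, so vaccination removes susceptibles at the effective rate
``sigma_a = sigma * a``.  Both the latent and the infective class transmit:
the force of infection is proportional to ``i + q e`` where ``q`` is the
relative infectiousness of the latent class.

Two formulations are provided:

* the absolute system in counts (S, E, I, R) with inflow ``b`` and outflow
  ``d``, see :func:`rhs_full`;
* the reduced proportional system in ``(s, e, i) = (S, E, I)/N`` obtained by
  normalising with the (non-constant) population size, see
  :func:`rhs_reduced`.  Its biologically meaningful region is the simplex

  ``T = {(s, e, i) : s >= 0, e >= 0, i >= 0, s + e + i <= 1}``.

The reduced right-hand side is

    s' = b - beta * s * (1 - sigma_a) * (i + q e) - (sigma_a + b) * s + alpha * s * i
    e' = beta * s * (1 - sigma_a) * (i + q e) - (b + epsilon) * e + alpha * e * i
    i' = epsilon * e - (alpha + gamma + b) * i + alpha * i**2

where ``alpha`` is the disease-induced death rate, ``gamma`` the recovery rate
and ``epsilon`` the progression rate out of the latent class.  All rates are
per unit time; the toolkit is unit-agnostic.

This module also provides the Jacobian of the reduced system and the second
additive compound of a 3x3 matrix, the building block of the Li-Muldowney
geometric stability criterion used in :mod:`seirvax.certificates`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence, Union

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "Parameters",
    "ProportionState",
    "AbsoluteState",
    "rhs_reduced",
    "rhs_full",
    "jacobian_reduced",
    "second_additive_compound",
]

_RATE_FIELDS = ("b", "alpha", "beta", "gamma", "epsilon", "sigma_a")


@dataclass(frozen=True)
class Parameters:
    """Rates of the SEIR model; all per unit time except the dimensionless ``q``.

    ``sigma_a`` (the product of vaccination rate and vaccine efficacy) is the
    primary vaccination field: the reduced system depends on vaccination only
    through this product.  ``sigma``, ``a`` and the outflow rate ``d`` are
    optional and needed only by the absolute system :func:`rhs_full`, whose
    incidence splits into an unvaccinated and a vaccinated-but-unprotected
    term.
    """

    b: float
    alpha: float
    beta: float
    gamma: float
    epsilon: float
    q: float
    sigma_a: float
    d: Optional[float] = None
    sigma: Optional[float] = None
    a: Optional[float] = None

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            v = float(v)
            object.__setattr__(self, f.name, v)
            if not math.isfinite(v):
                raise InvalidInputError(f"parameter {f.name!r} must be finite, got {v!r}")
            if v < 0:
                raise InvalidInputError(f"parameter {f.name!r} must be >= 0, got {v!r}")
        if self.sigma is not None and not (0.0 <= self.sigma <= 1.0):
            raise InvalidInputError(f"sigma must lie in [0, 1], got {self.sigma!r}")
        if self.sigma is not None and self.a is not None:
            prod = self.sigma * self.a
            if abs(prod - self.sigma_a) > 1e-12 * max(1.0, abs(self.sigma_a)):
                raise ConfigurationError(
                    f"sigma * a = {prod!r} is inconsistent with sigma_a = {self.sigma_a!r}"
                )

    @property
    def beta_eff(self) -> float:
        """Effective transmission coefficient of the reduced system, beta*(1 - sigma_a)."""
        return self.beta * (1.0 - self.sigma_a)

    def replace(self, **changes) -> "Parameters":
        return replace(self, **changes)

    def to_dict(self, drop_none: bool = True) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if drop_none:
            d = {k: v for k, v in d.items() if v is not None}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter key(s): {sorted(unknown)}")
        missing = {"b", "alpha", "beta", "gamma", "epsilon", "q", "sigma_a"} - set(d)
        if missing:
            raise ConfigurationError(f"missing required parameter key(s): {sorted(missing)}")
        return cls(**d)


@dataclass(frozen=True)
class ProportionState:
    """A point (s, e, i) of the reduced system; r = 1 - s - e - i is derived.

    Feasibility (membership of the simplex T) is a *flag*, not an enforcement:
    states outside T are representable so that solvers may explore and
    infeasible fixed points can be described.
    """

    s: float
    e: float
    i: float

    def __post_init__(self):
        for name in ("s", "e", "i"):
            v = float(getattr(self, name))
            object.__setattr__(self, name, v)
            if not math.isfinite(v):
                raise InvalidInputError(f"state component {name!r} must be finite, got {v!r}")

    @property
    def r(self) -> float:
        return 1.0 - self.s - self.e - self.i

    @property
    def feasible(self) -> bool:
        return self.is_feasible(tol=0.0)

    def is_feasible(self, tol: float = 0.0) -> bool:
        """Membership of T, optionally with slack ``tol`` for numerical states."""
        return (
            self.s >= -tol
            and self.e >= -tol
            and self.i >= -tol
            and self.s + self.e + self.i <= 1.0 + tol
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.s, self.e, self.i], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "ProportionState":
        y = np.asarray(y, dtype=float)
        if y.shape != (3,):
            raise InvalidInputError(f"expected a 3-vector (s, e, i), got shape {y.shape}")
        return cls(float(y[0]), float(y[1]), float(y[2]))


@dataclass(frozen=True)
class AbsoluteState:
    """A point (S, E, I, R) of the absolute system; N defaults to the class sum."""

    S: float
    E: float
    I: float
    R: float
    N: Optional[float] = None

    def __post_init__(self):
        total = float(self.S) + float(self.E) + float(self.I) + float(self.R)
        n = total if self.N is None else float(self.N)
        object.__setattr__(self, "N", n)
        for name in ("S", "E", "I", "R", "N"):
            v = float(getattr(self, name))
            object.__setattr__(self, name, v)
            if not math.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v!r}")
        if n <= 0:
            raise InvalidInputError(f"population size N must be > 0, got {n!r}")
        if abs(total - n) > 1e-9 * n:
            raise InvalidInputError(f"S + E + I + R = {total!r} does not close to N = {n!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.E, self.I, self.R], dtype=float)

    def proportions(self) -> ProportionState:
        return ProportionState(self.S / self.N, self.E / self.N, self.I / self.N)


StateLike = Union[ProportionState, Sequence[float], np.ndarray]


def _as_triple(state: StateLike) -> np.ndarray:
    if isinstance(state, ProportionState):
        return state.as_array()
    y = np.asarray(state, dtype=float)
    if y.shape != (3,):
        raise InvalidInputError(f"expected a 3-vector (s, e, i), got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise InvalidInputError(f"state must be finite, got {y!r}")
    return y


def rhs_reduced(state: StateLike, params: Parameters) -> np.ndarray:
    """Time derivatives (s', e', i') of the reduced proportional system.

    No clipping or projection is applied: the vector field is evaluated
    exactly as written, also outside the simplex T.
    """
    s, e, i = _as_triple(state)
    be = params.beta_eff
    inc = be * s * (i + params.q * e)
    return np.array(
        [
            params.b - inc - (params.sigma_a + params.b) * s + params.alpha * s * i,
            inc - (params.b + params.epsilon) * e + params.alpha * e * i,
            params.epsilon * e - (params.alpha + params.gamma + params.b) * i + params.alpha * i * i,
        ]
    )


def reduced_field(params: Parameters):
    """Return ``f(t, y)`` for ODE solvers, closing over validated parameters."""
    b = params.b
    be = params.beta_eff
    q = params.q
    sab = params.sigma_a + b
    beps = b + params.epsilon
    agb = params.alpha + params.gamma + b
    alpha = params.alpha
    eps = params.epsilon

    def f(t, y):
        s, e, i = y
        inc = be * s * (i + q * e)
        return (
            b - inc - sab * s + alpha * s * i,
            inc - beps * e + alpha * e * i,
            eps * e - agb * i + alpha * i * i,
        )

    return f


def rhs_full(state: AbsoluteState, params: Parameters) -> np.ndarray:
    """Time derivatives (S', E', I', R') of the absolute system.

    Requires ``sigma``, ``a`` and ``d`` individually: the incidence is
    ``F = beta*S*(1-a)*(I+qE)/N + beta*a*S*(1-sigma)*(I+qE)/N``, i.e. the sum
    of the unvaccinated and the vaccinated-but-unprotected contributions.
    The sum of the four derivatives equals ``(b - d) N - alpha I``, the growth
    of the total population.
    """
    if params.sigma is None or params.a is None:
        raise ConfigurationError("rhs_full requires sigma and a individually (not just sigma_a)")
    if params.d is None:
        raise ConfigurationError("rhs_full requires the outflow rate d")
    if not isinstance(state, AbsoluteState):
        raise InvalidInputError("rhs_full expects an AbsoluteState")
    S, E, I, R, N = state.S, state.E, state.I, state.R, state.N
    if N <= 0:
        raise InvalidInputError("population size N must be > 0")
    inc = (I + params.q * E) / N
    F = params.beta * S * (1.0 - params.a) * inc + params.beta * params.a * S * (1.0 - params.sigma) * inc
    sa = params.sigma * params.a
    return np.array(
        [
            params.b * N - F - (sa + params.d) * S,
            F - (params.d + params.epsilon) * E,
            params.epsilon * E - (params.alpha + params.gamma + params.d) * I,
            sa * S + params.gamma * I - params.d * R,
        ]
    )


def jacobian_reduced(state: StateLike, params: Parameters) -> np.ndarray:
    """Jacobian of :func:`rhs_reduced` at an arbitrary point."""
    s, e, i = _as_triple(state)
    be = params.beta_eff
    q = params.q
    alpha = params.alpha
    return np.array(
        [
            [
                -be * (i + q * e) - (params.sigma_a + params.b) + alpha * i,
                -q * be * s,
                alpha * s - be * s,
            ],
            [
                be * (i + q * e),
                q * be * s - (params.b + params.epsilon) + alpha * i,
                alpha * e + be * s,
            ],
            [
                0.0,
                params.epsilon,
                2.0 * alpha * i - (alpha + params.gamma + params.b),
            ],
        ]
    )


def second_additive_compound(J: np.ndarray) -> np.ndarray:
    """Second additive compound of a 3x3 matrix.

    For a 3x3 matrix the compound acts on 2-forms and its eigenvalues are the
    pairwise sums ``lambda_i + lambda_j`` (i < j) of the eigenvalues of ``J``.
    Computed from the generic definition::

        [[J11+J22,  J23,     -J13   ],
         [J32,      J11+J33,  J12   ],
         [-J31,     J21,      J22+J33]]
    """
    J = np.asarray(J, dtype=float)
    if J.shape != (3, 3):
        raise InvalidInputError(f"second additive compound needs a 3x3 matrix, got shape {J.shape}")
    if not np.all(np.isfinite(J)):
        raise InvalidInputError("matrix entries must be finite")
    return np.array(
        [
            [J[0, 0] + J[1, 1], J[1, 2], -J[0, 2]],
            [J[2, 1], J[0, 0] + J[2, 2], J[0, 1]],
            [-J[2, 0], J[1, 0], J[1, 1] + J[2, 2]],
        ]
    )
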