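"""Numerical integration of the model and oscillation detection.

The default integrator is adaptive Runge-Kutta 4(5) with rtol 1e-8 and atol
1e-10: the benchmark rates span 1e-5 to 5e-2, which makes fixed steps wasteful
but the system is not stiff enough to require implicit methods (LSODA is
available as a fallback through ``method=``).  States are never projected onto
the feasible simplex; violations beyond 1e-6 are logged as warnings.

Oscillations in the infective proportion are classified by peak analysis:
strict local maxima of i(t) exceeding the trajectory mean by a prominence
fraction (default 1% of the i range) count as peaks; with at least three
peaks, the ratio of the last to the first peak amplitude about the mean
decides between "sustained" (ratio within [0.9, 1.1]) and "damped"
(ratio < 0.9); everything else is "none".  These thresholds are tool
conventions, not model quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .equilibria import EquilibriumRecord, find_all_equilibria
from .exceptions import InvalidInputError, IntegrationError
from .model import (
    AbsoluteState,
    Parameters,
    ProportionState,
    reduced_field,
    rhs_full,
)

__all__ = [
    "Trajectory",
    "OscillationReport",
    "ScenarioResult",
    "integrate",
    "integrate_full",
    "detect_oscillations",
    "run_reference_scenario",
]

logger = logging.getLogger(__name__)

FEASIBILITY_WARN_TOL = 1e-6


@dataclass(frozen=True)
class Trajectory:
    """A sampled solution of the reduced (kind="reduced") or absolute (kind="full") system.

    ``states`` has one row per time point: columns (s, e, i) for the reduced
    system, (S, E, I, R) for the absolute one.
    """

    times: np.ndarray
    states: np.ndarray
    params: Parameters
    kind: str = "reduced"
    method: str = "RK45"
    rtol: float = 1e-8
    atol: float = 1e-10
    nfev: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)
        if t.ndim != 1 or y.ndim != 2 or len(t) != len(y):
            raise InvalidInputError("times and states must be matching 1-D/2-D arrays")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise InvalidInputError("trajectory samples must be finite")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def s(self) -> np.ndarray:
        return self.states[:, 0] if self.kind == "reduced" else self.states[:, 0] / self.N

    @property
    def e(self) -> np.ndarray:
        return self.states[:, 1] if self.kind == "reduced" else self.states[:, 1] / self.N

    @property
    def i(self) -> np.ndarray:
        return self.states[:, 2] if self.kind == "reduced" else self.states[:, 2] / self.N

    @property
    def r(self) -> np.ndarray:
        if self.kind == "reduced":
            return 1.0 - self.states.sum(axis=1)
        return self.states[:, 3] / self.N

    @property
    def N(self) -> np.ndarray:
        if self.kind != "full":
            raise InvalidInputError("N is defined only for trajectories of the absolute system")
        return self.states.sum(axis=1)

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_csv(self, path) -> None:
        """Write t, s, e, i, r at full double precision (shortest round-trip repr)."""
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t", "s", "e", "i", "r"])
            for t, s, e, i, r in zip(self.times, self.s, self.e, self.i, self.r):
                w.writerow([repr(float(t)), repr(float(s)), repr(float(e)), repr(float(i)), repr(float(r))])


@dataclass(frozen=True)
class OscillationReport:
    """Peak analysis of the infective proportion of a trajectory."""

    classification: str  # "none" | "damped" | "sustained"
    peak_times: Tuple[float, ...] = ()
    peak_values: Tuple[float, ...] = ()
    period: Optional[float] = None
    amplitude_trend_ratio: Optional[float] = None
    mean_level: float = 0.0

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "n_peaks": len(self.peak_times),
            "peak_times": list(self.peak_times),
            "peak_values": list(self.peak_values),
            "period": self.period,
            "amplitude_trend_ratio": self.amplitude_trend_ratio,
            "mean_level": self.mean_level,
        }


class ScenarioResult(NamedTuple):
    trajectory: Trajectory
    oscillation: OscillationReport
    equilibria: List[EquilibriumRecord]


def _solve(fun, t_span, y0, t_eval, method, rtol, atol):
    sol = solve_ivp(fun, t_span, y0, method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(
            f"integration failed: {sol.message}",
            last_time=float(sol.t[-1]) if len(sol.t) else None,
            last_state=sol.y[:, -1].copy() if sol.y.size else None,
        )
    return sol


def integrate(
    params: Parameters,
    init: ProportionState | Sequence[float],
    t_end: float,
    n_samples: int = 1000,
    t_eval: Optional[np.ndarray] = None,
    method: str = "RK45",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the reduced system from ``init`` to ``t_end``.

    ``t_eval`` overrides the uniform ``n_samples`` output grid.  Feasibility
    violations beyond 1e-6 are logged, not corrected.
    """
    if not t_end > 0:
        raise InvalidInputError(f"t_end must be > 0, got {t_end!r}")
    y0 = init.as_array() if isinstance(init, ProportionState) else np.asarray(init, dtype=float)
    if y0.shape != (3,) or not np.all(np.isfinite(y0)):
        raise InvalidInputError("initial state must be a finite 3-vector (s, e, i)")
    if t_eval is None:
        t_eval = np.linspace(0.0, float(t_end), int(n_samples))
    sol = _solve(reduced_field(params), (0.0, float(t_end)), y0, t_eval, method, rtol, atol)
    y = sol.y.T
    viol = max(
        float(np.maximum(-y, 0.0).max(initial=0.0)),
        float(np.maximum(y.sum(axis=1) - 1.0, 0.0).max(initial=0.0)),
    )
    if viol > FEASIBILITY_WARN_TOL:
        logger.warning("trajectory leaves the feasible simplex by up to %g", viol)
    return Trajectory(times=sol.t, states=y, params=params, kind="reduced",
                      method=method, rtol=rtol, atol=atol, nfev=int(sol.nfev))


def integrate_full(
    params: Parameters,
    init: AbsoluteState,
    t_end: float,
    n_samples: int = 1000,
    t_eval: Optional[np.ndarray] = None,
    method: str = "RK45",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the absolute system (S, E, I, R); requires sigma, a and d."""
    if not t_end > 0:
        raise InvalidInputError(f"t_end must be > 0, got {t_end!r}")
    if not isinstance(init, AbsoluteState):
        raise InvalidInputError("integrate_full expects an AbsoluteState")

    def fun(t, y):
        S, E, I, R = y
        n = S + E + I + R
        state = AbsoluteState.__new__(AbsoluteState)
        object.__setattr__(state, "S", S)
        object.__setattr__(state, "E", E)
        object.__setattr__(state, "I", I)
        object.__setattr__(state, "R", R)
        object.__setattr__(state, "N", n)
        return rhs_full(state, params)

    # trigger the sigma/a/d configuration check up front
    rhs_full(init, params)
    if t_eval is None:
        t_eval = np.linspace(0.0, float(t_end), int(n_samples))
    sol = _solve(fun, (0.0, float(t_end)), init.as_array(), t_eval, method, rtol, atol)
    return Trajectory(times=sol.t, states=sol.y.T, params=params, kind="full",
                      method=method, rtol=rtol, atol=atol, nfev=int(sol.nfev))


def detect_oscillations(
    traj: Trajectory,
    prominence_fraction: float = 0.01,
    sustained_band: Tuple[float, float] = (0.9, 1.1),
    min_samples: int = 100,
) -> OscillationReport:
    """Classify the i-component of a trajectory as none / damped / sustained."""
    if len(traj) < min_samples:
        raise InvalidInputError(f"need at least {min_samples} samples, got {len(traj)}")
    i_t = traj.i
    t = traj.times
    mean = float(i_t.mean())
    rng = float(i_t.max() - i_t.min())
    threshold = mean + prominence_fraction * rng
    idx, _ = find_peaks(i_t, height=threshold)
    peak_times = tuple(float(v) for v in t[idx])
    peak_values = tuple(float(v) for v in i_t[idx])
    period = None
    ratio = None
    classification = "none"
    if len(idx) >= 3:
        period = float(np.diff(t[idx]).mean())
        amps = i_t[idx] - mean
        ratio = float(amps[-1] / amps[0]) if amps[0] != 0 else None
        if ratio is not None:
            lo, hi = sustained_band
            if lo <= ratio <= hi:
                classification = "sustained"
            elif ratio < lo:
                classification = "damped"
    return OscillationReport(
        classification=classification,
        peak_times=peak_times,
        peak_values=peak_values,
        period=period,
        amplitude_trend_ratio=ratio,
        mean_level=mean,
    )


def run_reference_scenario(
    t_end: float,
    init: ProportionState | Sequence[float],
    n_samples: int = 10001,
    i_interval: Tuple[float, float] = (0.0, 1.0),
    method: str = "RK45",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ScenarioResult:
    """Fixed-point census, trajectory and oscillation report for the built-in benchmark.

    Horizon and initial condition are required arguments: the benchmark study
    does not state the ones behind its figures, so no default claims to
    replicate them.
    """
    from .scenarios import reference_parameters

    params = reference_parameters()
    traj = integrate(params, init, t_end, n_samples=n_samples, method=method, rtol=rtol, atol=atol)
    osc = detect_oscillations(traj)
    records = find_all_equilibria(params, i_interval)
    return ScenarioResult(trajectory=traj, oscillation=osc, equilibria=records)
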