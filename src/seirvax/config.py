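"""Run configuration: one flat YAML document per run.

A config document has up to five top-level blocks::

    parameters:      # all Parameters fields (b, alpha, beta, gamma, epsilon, q, sigma_a, ...)
    initial_state:   # s, e, i  (defaults to the disease-free equilibrium)
    solver:          # method, rtol, atol, t_end, n_samples
    analysis:        # i_min, i_max, prominence_fraction, sustained_low, sustained_high
    seed:            # integer driving any randomized utility

Unknown keys are rejected with an error naming the offending key; the fully
resolved configuration (defaults applied) is echoed to the log.  No cascading
includes: reproducibility over convenience.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from typing import Optional, Tuple

import yaml

from .equilibria import disease_free_equilibrium
from .exceptions import ConfigurationError
from .model import Parameters, ProportionState

__all__ = ["SolverConfig", "AnalysisConfig", "RunConfig", "load_config", "save_config"]

logger = logging.getLogger(__name__)


def _coerce(obj, name: str, typ):
    # YAML 1.1 reads "1.0e6" (no sign) as a string; be forgiving about numerics
    v = getattr(obj, name)
    try:
        object.__setattr__(obj, name, typ(v))
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"key {name!r} must be a {typ.__name__}, got {v!r}") from exc


@dataclass(frozen=True)
class SolverConfig:
    method: str = "RK45"
    rtol: float = 1e-8
    atol: float = 1e-10
    t_end: float = 1.0e6
    n_samples: int = 10001

    def __post_init__(self):
        for name in ("rtol", "atol", "t_end"):
            _coerce(self, name, float)
        _coerce(self, "n_samples", int)
        if self.t_end <= 0:
            raise ConfigurationError(f"solver.t_end must be > 0, got {self.t_end!r}")
        if self.n_samples < 2:
            raise ConfigurationError(f"solver.n_samples must be >= 2, got {self.n_samples!r}")
        if self.rtol <= 0 or self.atol <= 0:
            raise ConfigurationError("solver tolerances must be > 0")


@dataclass(frozen=True)
class AnalysisConfig:
    i_min: float = 0.0
    i_max: float = 1.0
    prominence_fraction: float = 0.01
    sustained_low: float = 0.9
    sustained_high: float = 1.1

    def __post_init__(self):
        for name in ("i_min", "i_max", "prominence_fraction", "sustained_low", "sustained_high"):
            _coerce(self, name, float)
        if not self.i_max > self.i_min:
            raise ConfigurationError("analysis.i_max must exceed analysis.i_min")
        if not 0.0 < self.prominence_fraction < 1.0:
            raise ConfigurationError("analysis.prominence_fraction must lie in (0, 1)")

    @property
    def i_interval(self) -> Tuple[float, float]:
        return (self.i_min, self.i_max)

    @property
    def sustained_band(self) -> Tuple[float, float]:
        return (self.sustained_low, self.sustained_high)


@dataclass(frozen=True)
class RunConfig:
    parameters: Parameters
    initial_state: ProportionState
    solver: SolverConfig = field(default_factory=SolverConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters.to_dict(),
            "initial_state": {"s": self.initial_state.s, "e": self.initial_state.e, "i": self.initial_state.i},
            "solver": asdict(self.solver),
            "analysis": asdict(self.analysis),
            "seed": self.seed,
        }


def _build_block(cls, block: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in block {name!r}")
    try:
        return cls(**block)
    except ConfigurationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid block {name!r}: {exc}") from exc


def config_from_dict(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigurationError("config document must be a mapping")
    allowed = {"parameters", "initial_state", "solver", "analysis", "seed"}
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
    if "parameters" not in doc:
        raise ConfigurationError("missing required block 'parameters'")
    try:
        params = Parameters.from_dict(dict(doc["parameters"]))
    except ConfigurationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid block 'parameters': {exc}") from exc
    if "initial_state" in doc:
        init = _build_block(ProportionState, dict(doc["initial_state"]), "initial_state")
    else:
        init = disease_free_equilibrium(params).location
        logger.info("initial_state not given; defaulting to the disease-free equilibrium %s", init)
    solver = _build_block(SolverConfig, dict(doc.get("solver", {})), "solver")
    analysis = _build_block(AnalysisConfig, dict(doc.get("analysis", {})), "analysis")
    seed = doc.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigurationError(f"seed must be an integer, got {seed!r}")
    return RunConfig(parameters=params, initial_state=init, solver=solver, analysis=analysis, seed=seed)


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    with open(path, "r") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"malformed config {path}: {exc}") from exc
    cfg = config_from_dict(doc if doc is not None else {})
    logger.info("resolved configuration:\n%s", yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
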