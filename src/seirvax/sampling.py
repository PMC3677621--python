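"""Random parameter sets for property-test suites.

Rates are drawn log-uniformly on [1e-5, 1] (the span of the benchmark rates)
and the relative latent infectiousness q uniformly on [0, 1]; named
constraints are enforced by rejection sampling.  Everything is a pure
function of the seed.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np

from .exceptions import ConfigurationError, InfeasibleConstraintsError
from .model import Parameters
from .thresholds import check_theorems, compute_R01

__all__ = ["sample_random_params", "CONSTRAINT_NAMES"]

logger = logging.getLogger(__name__)

CONSTRAINT_NAMES = ("R01<1", "R01>1", "b>=alpha", "theorem4")

MAX_REJECTIONS = 100_000


def _draw(rng: np.random.Generator) -> Parameters:
    b, alpha, beta, gamma, epsilon, sigma_a = 10.0 ** rng.uniform(-5.0, 0.0, size=6)
    q = rng.uniform(0.0, 1.0)
    return Parameters(b=b, alpha=alpha, beta=beta, gamma=gamma,
                      epsilon=epsilon, q=q, sigma_a=min(sigma_a, 0.999999))


def _satisfies(p: Parameters, constraint: str) -> bool:
    if constraint == "R01<1":
        return compute_R01(p) < 1.0
    if constraint == "R01>1":
        return compute_R01(p) > 1.0
    if constraint == "b>=alpha":
        return p.b >= p.alpha
    if constraint == "theorem4":
        return check_theorems(p).theorem4_applies
    raise ConfigurationError(
        f"unknown constraint {constraint!r}; known: {sorted(CONSTRAINT_NAMES)}"
    )


def sample_random_params(seed: int, constraints: Iterable[str] = ()) -> Parameters:
    """Deterministically sample a valid Parameters set satisfying ``constraints``.

    Raises :class:`InfeasibleConstraintsError` after 1e5 rejections.
    """
    constraints = tuple(constraints)
    for c in constraints:
        if c not in CONSTRAINT_NAMES:
            raise ConfigurationError(f"unknown constraint {c!r}; known: {sorted(CONSTRAINT_NAMES)}")
    rng = np.random.default_rng(seed)
    for n in range(1, MAX_REJECTIONS + 1):
        p = _draw(rng)
        if all(_satisfies(p, c) for c in constraints):
            logger.debug("accepted a parameter set after %d draw(s) (rate %.3g)", n, 1.0 / n)
            return p
    raise InfeasibleConstraintsError(
        f"no parameter set satisfying {constraints!r} in {MAX_REJECTIONS} draws"
    )
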