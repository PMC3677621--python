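"""Built-in benchmark parameter set.

The reference scenario describes a slowly renewed population (inflow
b = 1e-5 per unit time) facing a disease with a long infectious period
(gamma = 3e-3), moderate lethality (alpha = 2e-3), a latent class exactly as
infectious as the symptomatic one (q = 1) and a nearly ineffective
vaccination programme (sigma_a = 1e-6):

    epsilon = 0.05, gamma = 0.003, alpha = 0.002, beta = 0.05,
    q = 1, b = 0.00001, sigma_a = 0.000001.

With these rates R0 is close to 10, the disease-free point is unstable, and a
locally stable endemic equilibrium sits at small infective proportion.
"""

from __future__ import annotations

from .model import Parameters

__all__ = ["reference_parameters"]


def reference_parameters(**overrides) -> Parameters:
    """The built-in benchmark :class:`Parameters`; keyword overrides allowed.

    Pass e.g. ``d=1e-5, sigma=0.001, a=0.001`` to make the set usable with
    the absolute system as well.
    """
    base = dict(
        b=0.00001,
        alpha=0.002,
        beta=0.05,
        gamma=0.003,
        epsilon=0.05,
        q=1.0,
        sigma_a=0.000001,
    )
    base.update(overrides)
    return Parameters(**base)
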