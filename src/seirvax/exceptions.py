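"""Exception hierarchy for seirvax.

Everything raised on purpose derives from :class:`SeirvaxError`, so callers
(and the CLI) can catch one base class.  Validation failures additionally
derive from :class:`ValueError` to behave well with generic code.
"""


class SeirvaxError(Exception):
    """Base class for all errors raised by seirvax."""


class InvalidInputError(SeirvaxError, ValueError):
    """Non-finite, wrongly shaped or otherwise unusable numerical input."""


class ConfigurationError(SeirvaxError, ValueError):
    """A config document or parameter set is incomplete or inconsistent."""


class DegenerateParametersError(SeirvaxError, ValueError):
    """A formula's denominator vanishes for this parameter set."""


class DomainError(SeirvaxError, ValueError):
    """Input lies outside the mathematical domain of the operation."""


class AmbiguousRootsError(SeirvaxError, RuntimeError):
    """Several endemic roots were found where exactly one was expected.

    The offending roots are attached as ``roots`` so callers can inspect
    the full census instead of a single point.
    """

    def __init__(self, roots, message=None):
        self.roots = list(roots)
        super().__init__(
            message or f"expected a unique endemic root in (0, 1), found {len(self.roots)}: {self.roots}"
        )


class IntegrationError(SeirvaxError, RuntimeError):
    """The ODE solver failed; carries the last valid time and state."""

    def __init__(self, message, last_time=None, last_state=None):
        self.last_time = last_time
        self.last_state = last_state
        super().__init__(message)


class InfeasibleConstraintsError(SeirvaxError, RuntimeError):
    """Rejection sampling exhausted its budget without satisfying constraints."""
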