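"""Exception hierarchy shared across the package."""


class SSIOError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SSIOError):
    """A delimited input file could not be parsed."""


class DuplicateGeneError(ParseError):
    """An expression table contains a repeated gene identifier."""


class InsufficientDataError(SSIOError):
    """Fewer samples/timepoints than an operation requires."""


class ExtrapolationError(SSIOError):
    """A requested time lies outside the observed range."""


class EmptyInputError(SSIOError):
    """An operation received an empty matrix or vector."""


class ConfigError(SSIOError):
    """An unknown option, variant or malformed configuration block."""


class DegenerateDirectionError(SSIOError):
    """A PLS direction vector produced zero scores."""


class MissingRegulatorError(SSIOError):
    """A regulator required by the network has no expression/signal level."""


class InvalidKineticsError(SSIOError):
    """Kinetic coefficients must be strictly positive."""


class IntegrationError(SSIOError):
    """The ODE solver failed; message carries the solver diagnostic."""


class EquilibriumNotFoundError(SSIOError):
    """Trust-region polishing did not converge to a fixed point."""


class FitError(SSIOError):
    """Parameter optimization failed for a gene or the whole loop."""


class KeyMismatchError(SSIOError):
    """Two weight vectors do not share the same (target, regulator) keys."""
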