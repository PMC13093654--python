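"""Exception hierarchy shared across the package."""


class CaroteetError(Exception):
    """Base class for all package errors."""


class DomainError(CaroteetError, ValueError):
    """An input lies outside the physically meaningful domain."""


class ConfigurationError(CaroteetError, ValueError):
    """An unknown identifier, missing registry entry, or malformed config."""


class ContractError(CaroteetError, ValueError):
    """An argument violates an interface contract (e.g. non-normalized spectrum)."""


class ConvergenceError(CaroteetError, RuntimeError):
    """A numerical procedure did not damp/converge on the supplied grid."""
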