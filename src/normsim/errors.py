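"""Package exception hierarchy."""


class NormError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NormError, ValueError):
    """Inconsistent model specification, parameters, or configuration input."""


class DomainError(NormError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class NumericalError(NormError, RuntimeError):
    """An integrator or quadrature routine failed to meet its tolerance."""
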