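"""Exception types shared across the package."""


class SecretomicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SecretomicsError, ValueError):
    """Invalid configuration: bad fractions, mismatched dimensions, etc."""


class DesignError(SecretomicsError, ValueError):
    """A study design that cannot support the requested operation."""


class NumericalError(SecretomicsError, ArithmeticError):
    """Singular or ill-conditioned linear systems, degenerate fits."""


class DomainError(SecretomicsError, ValueError):
    """Input values outside the mathematically valid domain."""


class CalibrationError(SecretomicsError, ValueError):
    """FPR calibration is impossible with the provided controls."""


class ParseError(SecretomicsError, ValueError):
    """A file that does not conform to its declared dialect."""
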