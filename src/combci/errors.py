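"""Exception hierarchy shared across the package."""


class CombciError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CombciError, ValueError):
    """An input lies outside the mathematical domain of the operation."""


class FitError(CombciError, RuntimeError):
    """A distribution fit failed to converge or its residual exceeds tolerance.

    Attributes
    ----------
    residual : float or None
        The achieved quantile-match discrepancy, when available.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class CombinationError(CombciError, RuntimeError):
    """The combination function produced too many invalid values.

    Attributes
    ----------
    bad_fraction : float or None
        Fraction of bootstrap draws for which the combined value was
        non-finite (or otherwise invalid).
    """

    def __init__(self, message: str, bad_fraction: float | None = None):
        super().__init__(message)
        self.bad_fraction = bad_fraction


class ExpressionError(CombciError, ValueError):
    """A combination expression failed to parse or references unknown names."""
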