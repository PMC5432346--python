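"""Exception and warning hierarchy.

Exit-code mapping used by the CLI: ConfigurationError -> 2,
DataValidationError -> 3, NumericalError -> 4.
"""


class CvasdError(Exception):
    """Base class for package errors."""


class ConfigurationError(CvasdError):
    """Bad configuration: missing column mapping, invalid grids, ..."""


class DataValidationError(CvasdError):
    """Input data violates a contract (non-binary event, empty merge, ...)."""


class NumericalError(CvasdError):
    """A numerical procedure failed in a way that cannot be flagged-and-continued."""


class CollinearityError(NumericalError):
    """Design matrix is rank deficient (beyond single degenerate columns)."""


class ConvergenceWarning(UserWarning):
    """A fit did not converge; the result is flagged, not silently dropped."""


class MonotoneLikelihoodWarning(ConvergenceWarning):
    """Cox partial likelihood has no finite maximizer (perfect separation of risk order)."""
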