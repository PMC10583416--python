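"""Exception hierarchy shared across the package."""


class MedimrError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MedimrError, ValueError):
    """Malformed input file: missing columns, non-square LD matrix, out-of-range entries."""


class EmptyOverlapError(MedimrError, ValueError):
    """No shared variants between trait summary-statistic sets."""


class InsufficientInstrumentsError(MedimrError, ValueError):
    """An estimator received fewer variants than its minimum."""


class CollinearityError(MedimrError, ValueError):
    """Exposure effect matrix is rank deficient in multivariable MR."""

    def __init__(self, message: str, exposures: list[str] | None = None):
        super().__init__(message)
        self.exposures = exposures or []


class DomainError(MedimrError, ValueError):
    """A numeric argument lies outside its mathematical domain (se <= 0, m < 1, ...)."""
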