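"""Exception hierarchy for the mosaicism pipeline."""


class CagMosaicError(Exception):
    """Base class for all package-specific errors."""


class PeakTableFormatError(CagMosaicError):
    """A peak table is missing a mandatory column or cannot be parsed."""


class PeakRowParseError(CagMosaicError):
    """A single row of a peak table holds a non-numeric size or height."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class CalibrationError(CagMosaicError):
    """A size calibration is invalid or maps a peak to a repeat count < 1."""


class EmptyWindowError(CagMosaicError):
    """No peak of the trace falls inside the expanded-allele CAG window."""


class MissingModalPeakError(CagMosaicError):
    """The reference modal peak is absent (or has zero height) in a trace.

    Usually signals a mismatch between the per-individual reference modal
    and the trace; resolve by re-calling the modal peak on the trace.
    """


class InsufficientDataError(CagMosaicError):
    """Too few observations for the requested regression."""


class UndefinedCorrelationError(CagMosaicError):
    """Pearson correlation undefined (zero variance in one variable)."""


class RankDeficientError(CagMosaicError):
    """Residualization design matrix is rank deficient (collinear columns)."""


class PairingError(CagMosaicError):
    """Ct records to be combined do not share individual and target gene."""


class BaselineMissingError(CagMosaicError):
    """No cerebellum baseline Ct record available for an individual."""


class TargetUnreachableError(CagMosaicError):
    """A requested ground-truth expansion index exceeds the achievable range."""
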