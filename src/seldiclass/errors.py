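"""Exception hierarchy for the seldiclass pipeline.

All package errors derive from :class:`SeldiClassError` so callers can catch
one base class.  The CLI maps subtrees to exit codes: configuration problems
exit 2, data/format problems exit 3, numeric failures exit 4.
"""


class SeldiClassError(Exception):
    """Base class for all seldiclass errors."""


class ConfigError(SeldiClassError):
    """A configuration value violates its documented constraints."""


class DataError(SeldiClassError):
    """Input data violates a contract (bad label, length mismatch, ...)."""


class FormatError(DataError):
    """A CSV file does not follow the expected dialect."""


class AlignmentError(DataError):
    """Two spectra do not share an identical m/z grid."""


class ManifestError(DataError):
    """The label manifest does not cover (or mislabels) a sample."""


class InsufficientDataError(DataError):
    """A group-wise operation was asked of a class with too few samples."""


class ShapeError(DataError):
    """An array has a shape inconsistent with the model or grid."""


class DimensionalityError(DataError):
    """LDA requires fewer features than observations; violated here."""


class UndefinedMetricError(SeldiClassError):
    """A performance metric has an empty denominator (no positives, ...)."""


class NumericError(SeldiClassError):
    """A numerical operation failed (singular matrix, ...)."""


class DivergenceError(NumericError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")
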