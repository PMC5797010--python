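"""Exception types shared across the pipeline."""


class QScreenError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(QScreenError, ValueError):
    """A parameter violates its documented precondition."""


class LayoutError(QScreenError, ValueError):
    """Plate layout and dilution series (or well map) are inconsistent."""


class QCError(QScreenError, ValueError):
    """A plate cannot be quality-controlled (e.g. too few control wells)."""


class UndefinedMetricError(QScreenError, ArithmeticError):
    """A QC metric is undefined for the given control statistics."""


class DataIntegrityError(QScreenError, ValueError):
    """Duplicate or contradictory records in assembled screen data."""


class FitError(QScreenError, ValueError):
    """A concentration-response series cannot be fitted."""


class SchemaError(QScreenError, KeyError):
    """An identifier is missing from the expected universe (cell line, column...)."""
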