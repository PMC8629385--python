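"""Named exception types raised across the toolkit."""


class DevomicsError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(DevomicsError):
    """Invalid input data or configuration."""


class DuplicateGeneError(ValidationError):
    """An expression table contains a repeated gene id."""


class ColumnMismatchError(ValidationError):
    """Expression columns and time-point metadata disagree."""


class NegativeAbundanceError(ValidationError):
    """An abundance value is negative."""


class MissingExpressionError(ValidationError):
    """An id referenced by a pair/triplet has no expression row."""


class MissingSampleError(ValidationError):
    """A sample requested for a population is absent from the VCF."""


class AnnotationParseError(ValidationError):
    """A gene-annotation line (BED/GFF3) could not be parsed."""


class MissingUpstreamError(DevomicsError):
    """A pipeline stage was requested before its inputs exist."""
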