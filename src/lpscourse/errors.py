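"""Exception hierarchy shared across the pipeline."""


class LpscourseError(Exception):
    """Base class for all package errors."""


class ConfigError(LpscourseError):
    """Invalid simulation or pipeline configuration; names the offending field."""


class ParseError(LpscourseError):
    """Malformed on-disk input; carries the file and line number where known."""


class SchemaError(LpscourseError):
    """Structurally valid file whose content violates a schema contract
    (duplicate ids, missing columns, promoters mapped to two genes, ...)."""


class CoordinateError(LpscourseError):
    """Genomic coordinates outside declared bounds or inverted intervals."""


class NormalizationError(LpscourseError):
    """Normalization cannot proceed (zero-sum library, double normalization)."""


class AnalysisError(LpscourseError):
    """An analysis stage received input it cannot meaningfully process."""
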