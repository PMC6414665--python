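"""Exception hierarchy shared across the package."""


class MFRError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MFRError):
    """Input violates a documented invariant (duplicate ids, bad label, cycle...)."""


class ParseError(MFRError):
    """Malformed file content; message carries row/column coordinates where known."""


class SchemaError(MFRError):
    """Serialized model file is missing required fields or is truncated."""


class LookupError_(MFRError):
    """Requested gene/term is absent from the resource."""


class UndefinedCorrelationError(MFRError):
    """Correlation undefined (zero variance / empty residual); caller decides imputation."""


class MissingFeatureError(MFRError):
    """A knowledge feature cannot be computed for this pair (unannotated gene etc.)."""


class SizeError(MFRError):
    """Input too small for the requested computation."""
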