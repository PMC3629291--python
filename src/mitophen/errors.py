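"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data violate the phenotype-database contracts."""


class UndefinedSimilarityError(ValidationError):
    """Raised when a correlation-type similarity is undefined (e.g. an
    all-zero symptom vector, or zero variance)."""
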