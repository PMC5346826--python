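"""Exception hierarchy for the CRC decision-support library."""


class CdssError(Exception):
    """Base class for all library errors."""


class SchemaError(CdssError):
    """Codebook source is structurally invalid (e.g. duplicate field names)."""


class CodeCollisionError(SchemaError):
    """Two labels within one field share an integer code."""

    def __init__(self, field: str, code: int):
        self.field = field
        self.code = code
        super().__init__(f"field {field!r}: integer code {code} assigned to more than one label")


class EncodingError(CdssError):
    """A record label cannot be mapped through the codebook."""


class DecodingError(CdssError):
    """A vector entry is not a known code for its field."""


class DateError(CdssError, ValueError):
    """Invalid or unparseable Persian calendar date."""


class AlignmentError(CdssError):
    """Two feature vectors are not comparable (length or mask mismatch)."""


class UndefinedSimilarityError(CdssError):
    """Cosine similarity is undefined (both vectors have zero norm)."""


class EmptyOverlapError(CdssError):
    """No shared non-missing slots between two encoded vectors."""


class InsufficientReferenceError(CdssError):
    """The registry holds no reference patients usable by the requested estimator mode."""


class ConfigurationError(CdssError):
    """A rule table or configuration document does not cover a required case."""


class QueryError(CdssError):
    """A search request uses an unknown criterion."""


class RegistryLookupError(CdssError, KeyError):
    """Referenced patient_id is not present in the registry."""
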