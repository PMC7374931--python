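"""Exception hierarchy shared across the package."""


class SLContologyError(Exception):
    """Base class for all package errors."""


class SchemaError(SLContologyError):
    """A required column or field is missing from an input table."""


class IntegrityError(SLContologyError):
    """An internal consistency contract was violated (duplicate keys,
    residual cycles, pruned substrate nodes, ...)."""


class VocabularyError(SLContologyError):
    """A value falls outside a closed controlled vocabulary."""


class ParseError(SLContologyError):
    """An input file could not be parsed."""


class MappingError(SLContologyError):
    """Substrate-to-term mapping failed entirely."""


class TopologyError(SLContologyError):
    """Protein topology annotation is invalid (overlaps, out of range)."""


class SequenceError(SLContologyError):
    """Protein sequence contains characters outside the tolerated alphabet."""
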