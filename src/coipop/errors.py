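"""Exception hierarchy shared across the pipeline stages."""


class CoipopError(Exception):
    """Base class for all package errors."""


class ParseError(CoipopError):
    """Malformed input file (FASTA syntax, illegal characters)."""


class DataError(CoipopError):
    """Structurally valid input that violates a data contract."""


class ConfigurationError(CoipopError):
    """Invalid or incomplete configuration."""


class GenerationError(CoipopError):
    """Synthetic-data generation could not satisfy its constraints."""


class ExtractionError(CoipopError):
    """No acceptable primer pair / amplicon found in a sequence."""


class DigestionError(CoipopError):
    """In-silico digestion undecidable (ambiguity code at a potential site)."""
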