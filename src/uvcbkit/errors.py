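"""Exception hierarchy shared across the toolkit."""


class UvcbError(Exception):
    """Base class for all toolkit errors."""


class DesignSchemaError(UvcbError):
    """A design/config file does not conform to the documented schema."""


class ChemistryError(UvcbError):
    """A line notation failed to parse or a chemical operation failed."""


class DesignValidationError(UvcbError):
    """A design entry violates a declared invariant (e.g. wrong group class)."""


class AttachmentError(UvcbError):
    """A substitution was requested at a position without available valence."""


class ConfigurationError(UvcbError):
    """Inconsistent or incomplete run configuration."""


class MissingDataError(UvcbError):
    """An operation requires data (endpoint, reference value) that is absent."""


class DegenerateNeighborhoodError(UvcbError):
    """All analog similarities are zero; a weighted mean is undefined."""
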