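"""Exception hierarchy for the sidefx package."""


class SidefxError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SidefxError):
    """An input file is missing a mandatory column or has an invalid layout."""


class ConsistencyError(SidefxError):
    """An input violates a data-model invariant (e.g. endorsement without exposure)."""


class RecordError(SidefxError):
    """A single record in an input file is malformed; carries the line context."""


class ConfigError(SidefxError):
    """Invalid run or simulation configuration."""
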