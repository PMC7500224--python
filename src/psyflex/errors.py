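"""Exception types shared across the package."""


class PsyflexError(Exception):
    """Base class for package errors."""


class DesignConstraintError(PsyflexError):
    """A paradigm design request cannot satisfy its placement/count constraints.

    The message names the violated bound.
    """


class ConfigurationError(PsyflexError):
    """An invalid population or analysis configuration (e.g. a loading with
    squared magnitude above 1, leaving negative unique variance)."""


class SchemaError(PsyflexError):
    """A trial log or index table file does not match the documented schema."""
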