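"""Exception hierarchy shared across the package."""


class TreburdenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TreburdenError, ValueError):
    """A configuration value violates an invariant; message names the field."""


class SchemaError(TreburdenError, ValueError):
    """An input table is missing required columns."""


class ParseError(TreburdenError, ValueError):
    """A row or record could not be parsed; message carries the line number."""


class DegenerateDataError(TreburdenError, ValueError):
    """Input data admit no meaningful estimate (constant predictor, empty group...)."""
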