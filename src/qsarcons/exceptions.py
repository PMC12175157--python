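"""Exception types raised across qsarcons."""


class ValidationError(ValueError):
    """An input value violates a documented contract (range, shape, vocabulary)."""


class TableFormatError(ValidationError):
    """A prediction table or bit matrix does not match the file contract."""


class ConfigError(ValidationError):
    """A synthetic-data or run configuration carries an invalid value."""
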