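"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration object or parameter is invalid."""


class SchemaError(ValueError):
    """A record table does not conform to its declared schema."""
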