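"""Exception types shared across the pipeline stages."""


class BsaQtlError(ValueError):
    """Base class for all pipeline errors."""


class ConfigError(BsaQtlError):
    """Invalid configuration or operation parameters."""


class DataError(BsaQtlError):
    """Malformed, inconsistent or out-of-contract input data."""


class FormatError(BsaQtlError):
    """A file does not conform to the expected on-disk format."""
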