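"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid model / training configuration."""


class ShapeError(ValueError):
    """Array shapes incompatible with the requested operation."""
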