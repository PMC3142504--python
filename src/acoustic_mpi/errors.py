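"""Exception types shared across the package."""


class DomainError(ValueError):
    """A physical quantity is outside its admissible domain."""


class ConfigError(ValueError):
    """A configuration key, value or numerical setting is invalid."""
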