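"""Exception types shared across the package."""


class ConfigError(ValueError):
    """An argument or configuration value violates a documented contract."""


class ParseError(ValueError):
    """An input file or table row could not be interpreted."""
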