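"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when an operation receives invalid parameters or malformed input."""


class InsufficientDataError(ValueError):
    """Raised when a statistical operation has too few observations to proceed."""
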