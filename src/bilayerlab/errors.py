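"""Exception and warning types shared across the toolkit."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed or uses an unsupported layout."""


class UnwrapAmbiguityWarning(UserWarning):
    """Emitted when a per-frame displacement reaches half a box length.

    At that point the minimum-image convention can no longer decide which
    periodic image a particle moved to, so the unwrapped path may be wrong.
    """
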