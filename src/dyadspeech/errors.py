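"""Exception types shared across the package."""


class DyadSpeechError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DyadSpeechError):
    """Raised when input data violate a structural precondition."""


class ParseError(DyadSpeechError):
    """Raised when a file cannot be parsed; carries row/line context."""


class UndefinedFeatureError(DyadSpeechError):
    """Raised when a speech feature is undefined for a session.

    The ``reason`` attribute carries a short machine-readable explanation
    (e.g. ``"no valid frames"``) that downstream code records alongside the
    missing value instead of silently imputing.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
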