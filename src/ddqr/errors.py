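"""Exception hierarchy for the ddqr package."""


class DdqrError(Exception):
    """Base class for all ddqr errors."""


class EmptySequenceError(DdqrError):
    """Raised when an input sequence is empty after whitespace stripping."""


class InvalidBaseError(DdqrError):
    """Raised on a character outside the strict {A,C,G,T} alphabet.

    Ambiguity codes (N, R, Y, ...) and gaps are rejected rather than
    silently dropped: a codec must not lose data.
    """

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 1-based
        super().__init__(
            f"invalid base {char!r} at position {position}: "
            "only A, C, G, T are supported"
        )


class InvalidBase64Error(DdqrError):
    """Raised on a character outside the RFC 4648 standard Base64 alphabet."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position  # 1-based
        super().__init__(f"invalid Base64 character {char!r} at position {position}")


class CorruptHeaderError(DdqrError):
    """Raised when a decoded bitstream header violates the DDQR format."""


class CapacityExceededError(DdqrError):
    """Raised when a payload does not fit any QR version at the chosen EC level."""

    def __init__(self, payload_len: int, max_chars: int, ec_level: str):
        self.payload_len = payload_len
        self.max_chars = max_chars
        self.ec_level = ec_level
        super().__init__(
            f"payload of {payload_len} characters exceeds QR version-40 "
            f"capacity of {max_chars} at error-correction level {ec_level}"
        )


class NoSymbolError(DdqrError):
    """Raised when no QR symbol is found in an image."""


class AmbiguousSymbolError(DdqrError):
    """Raised when an image contains more than one QR symbol."""


class QrDecodeError(DdqrError):
    """Raised when a located QR symbol cannot be decoded (damage beyond EC)."""


class ParseError(DdqrError):
    """Raised on malformed FASTA input."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InsufficientDataError(DdqrError):
    """Raised when a ratio series is too short for the sliding-window scan."""
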