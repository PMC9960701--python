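"""Exception hierarchy for cardiohrv."""


class CardioHRVError(Exception):
    """Base class for all cardiohrv errors."""


class InvalidConfigError(CardioHRVError, ValueError):
    """A synthetic or run configuration violates its invariants."""


class ParseError(CardioHRVError, ValueError):
    """A text recording/annotation/IBI file could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class OverlapError(CardioHRVError, ValueError):
    """AO latency plus jitter would collide with the next beat."""


class ValidationError(CardioHRVError, ValueError):
    """A domain object violates its invariants."""
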