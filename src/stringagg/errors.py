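"""Exception hierarchy shared across the package."""


class StringaggError(Exception):
    """Base class for all package-specific errors."""


class InputError(StringaggError):
    """A user-supplied file or value is unusable (empty file, bad fold change...)."""


class FormatError(StringaggError):
    """A delimited file does not follow the expected layout."""


class ProtocolError(StringaggError):
    """An enrichment payload is malformed (missing or invalid fields)."""


class RetrievalError(StringaggError):
    """Enrichment retrieval failed for one comparison after retries."""

    def __init__(self, message: str, label: str | None = None):
        super().__init__(message)
        self.label = label


class UsageError(StringaggError):
    """Options were combined in an unsupported way."""
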