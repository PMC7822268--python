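"""Exception hierarchy shared across the package."""


class OligopipeError(Exception):
    """Base class for all package errors."""


class InvalidSequenceError(OligopipeError, ValueError):
    """Sequence contains a character outside the working alphabet."""


class LengthMismatchError(OligopipeError, ValueError):
    """Two sequences that must be equal length are not."""


class EmptyInputError(OligopipeError, ValueError):
    """An operation received an empty sequence or collection it cannot handle."""


class DesignTypeError(OligopipeError, ValueError):
    """An operation was called on the wrong design type (ASO vs siRNA)."""


class FormatError(OligopipeError, ValueError):
    """A file violates its declared format; message carries the line number."""


class DuplicateRecordError(FormatError):
    """Two records in one file share an identifier."""


class EmptyEnumerationError(OligopipeError, ValueError):
    """Transcript shorter than the requested oligo length."""


class EmptyDatabaseError(OligopipeError, ValueError):
    """An off-target database with no sequences."""


class QueryTooShortError(OligopipeError, ValueError):
    """Query too short for the pigeonhole segment scheme."""


class ConfigurationError(OligopipeError, ValueError):
    """A run/selection configuration is inconsistent or incomplete."""


class MissingPropertyError(OligopipeError, KeyError):
    """A required candidate property is absent or non-numeric."""


class DependencyError(OligopipeError, ValueError):
    """A stage was invoked before the stage that produces its inputs."""


class NotationError(OligopipeError, ValueError):
    """HELM-dialect parse or registry violation; message carries the offset."""
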