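"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`EEGSplitError`
so callers can catch package errors without also swallowing programming
mistakes (plain ``TypeError`` etc. propagate unchanged).
"""


class EEGSplitError(Exception):
    """Base class for all errors raised by eegsplit."""


class InputError(EEGSplitError, ValueError):
    """Invalid data passed to an operation (bad label, shape mismatch...)."""


class ConfigError(EEGSplitError, ValueError):
    """Invalid configuration object (e.g. d_model not divisible by heads)."""


class FormatError(EEGSplitError, ValueError):
    """A file exists but does not satisfy the expected format/contents."""


class FileIOError(EEGSplitError, OSError):
    """A file could not be read or written."""


class StateError(EEGSplitError, RuntimeError):
    """An operation was called in the wrong protocol phase."""
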