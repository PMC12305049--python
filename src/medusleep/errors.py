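"""Exception types shared across the package."""


class MedusleepError(Exception):
    """Base class for package errors."""


class RejectedInputError(MedusleepError, ValueError):
    """An input value violates a precondition (non-positive duration, empty ROI, ...)."""


class FormatError(MedusleepError, ValueError):
    """A file or array does not have the expected layout (ragged stack, bad CSV, ...)."""


class InsufficientDataError(MedusleepError, ValueError):
    """Too few observations to compute the requested quantity."""


class MissingScheduleError(MedusleepError, ValueError):
    """A deprivation condition was requested without a stimulus schedule."""


class ConfigError(MedusleepError, ValueError):
    """A run configuration failed validation; the message names the offending field."""
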