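"""Exception hierarchy.

Every error raised by the pipeline derives from :class:`TremorkitError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors with a single ``except`` clause.
"""


class TremorkitError(Exception):
    """Base class for all tremorkit errors."""


class FormatError(TremorkitError):
    """A file does not match the expected CSV dialect (missing columns, no header)."""


class DataError(TremorkitError):
    """A file parsed but its contents are unusable (NaNs, too few samples)."""


class ParameterError(TremorkitError):
    """A processing parameter is out of its valid range."""


class DegenerateSignalError(TremorkitError):
    """An operation's input signal has no variation where variation is required."""


class AlignmentError(TremorkitError):
    """Inter-device synchronization could not be established."""


class ClassificationError(TremorkitError):
    """A cutoff rule references a feature that is missing from the feature set."""


class ConsistencyError(TremorkitError):
    """Inputs that must share provenance (e.g. transform chains) do not."""
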