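"""Exception hierarchy shared by all modules.

Exit-code mapping used by the CLI: InvalidParameterError -> 2,
NewickFormatError -> 3, VerificationError -> 4. ConsistencyError signals a
violated exact identity, i.e. a bug, and is never converted to a soft failure.
"""


class CoalgrowError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CoalgrowError, ValueError):
    """A numeric or structural argument is outside its documented domain."""


class InvalidStateError(CoalgrowError, RuntimeError):
    """An object is not in the state an operation requires (e.g. nonzero tip heights)."""


class NewickFormatError(CoalgrowError, ValueError):
    """Input tree text is malformed, non-binary or non-ultrametric."""


class ConsistencyError(CoalgrowError, RuntimeError):
    """An exact bookkeeping identity failed: internal bug, not sampling noise."""


class VerificationError(CoalgrowError, RuntimeError):
    """A Monte-Carlo verification run exceeded its allowed z-score budget."""
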