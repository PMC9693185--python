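"""Exception hierarchy.

All data-facing errors derive from :class:`SkelSuiteError` so callers (and
the CLI) can distinguish bad input from genuine bugs.
"""


class SkelSuiteError(Exception):
    """Base class for all toolkit errors."""


class SkeletonError(SkelSuiteError):
    """Invalid skeleton definition (cyclic tree, dangling bone, ...)."""


class PoseParseError(SkelSuiteError):
    """Malformed pose file; message names the offending frame/joint."""


class TrackParseError(SkelSuiteError):
    """Malformed tracking file; message names the offending line."""


class ValidationError(SkelSuiteError):
    """An in-memory object violates its invariants."""


class DegenerateInputError(SkelSuiteError):
    """Operation impossible on this input (all joints hidden, zero-length
    bone, too few points for alignment, ...)."""
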