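"""Exception hierarchy for corpus I/O and validation."""


class BodyCuesError(Exception):
    """Base class for all package-specific errors."""


class SkeletonError(BodyCuesError):
    """Invalid skeleton definition (wrong counts, broken tree, bad pairing)."""


class SessionFormatError(BodyCuesError):
    """A session file does not conform to the expected dialect."""


class ColumnCountError(SessionFormatError):
    """A session file has the wrong number of columns."""


class NonNumericError(SessionFormatError):
    """A session file contains cells that cannot be parsed as numbers."""


class UnmappedJointError(SessionFormatError):
    """A required canonical joint has no column in the input file."""


class ManifestError(BodyCuesError):
    """A corpus manifest is malformed."""


class DuplicateSessionError(ManifestError):
    """A manifest lists more than one session for an (interviewee, kind) pair."""


class UnknownConditionError(ManifestError):
    """A manifest row carries a condition token other than truth/lie/unknown."""


class ZeroLengthSegmentError(BodyCuesError):
    """A parent-child segment has zero length, so its direction is undefined."""
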