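"""Exception hierarchy.

All data-level failures derive from :class:`CurvatraceError` so callers (and
the command-line wrapper) can distinguish bad input from programming errors.
Messages start with the short contract phrase ("segment too short", "parse
error", ...) followed by context.
"""


class CurvatraceError(Exception):
    """Base class for all data and geometry errors raised by this package."""


class SegmentTooShortError(CurvatraceError):
    """A contiguous trace segment has fewer residues than a cubic spline needs."""


class UnsortedTraceError(CurvatraceError):
    """Residue identifiers are not strictly increasing."""


class InvalidCoordinateError(CurvatraceError):
    """A coordinate is NaN or infinite."""


class ParameterOutOfRangeError(CurvatraceError):
    """A curve parameter lies outside every fitted segment."""


class DegenerateParameterizationError(CurvatraceError):
    """The curve speed |r'| vanishes at the requested parameter."""


class UndefinedDescriptorError(CurvatraceError):
    """A descriptor is requested where it is flagged undefined."""


class DegenerateSegmentError(CurvatraceError):
    """A writhe segment has (near-)zero length."""


class UndefinedWindowError(CurvatraceError):
    """A writhe window does not fit inside one contiguous segment."""


class EmptyTraceError(CurvatraceError):
    """A structure file contains no C-alpha atoms."""


class PDBParseError(CurvatraceError):
    """A fixed-width PDB record could not be parsed (message carries the line number)."""


class AlignmentMismatchError(CurvatraceError):
    """An alignment sequence disagrees with its structure's residue sequence."""


class NothingToClusterError(CurvatraceError):
    """Every alignment column has undefined descriptors."""


class MalformedTableError(CurvatraceError):
    """A propensity-table file has the wrong shape or non-numeric entries."""


class InvalidFixtureSpecError(CurvatraceError):
    """A synthetic-fixture specification has invalid parameters."""
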