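"""Exception hierarchy shared across the package."""


class MeripQCError(Exception):
    """Base class for all package errors."""


class GTFParseError(MeripQCError):
    """A GTF line could not be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"GTF parse error at line {lineno}: {message}")


class EmptyAnnotationError(MeripQCError):
    """The annotation contains no exon features (or no gene models)."""


class MissingIndexError(MeripQCError):
    """A BAM file has no .bai index."""


class DepthError(MeripQCError):
    """Requested down-sampling depth exceeds the available reads."""


class ContigMismatchError(MeripQCError):
    """Most reads map to chromosomes absent from the annotation."""


class RoleError(MeripQCError):
    """Sample roles are inconsistent for the requested operation."""


class ShapeError(MeripQCError):
    """Bin indices / matrix shapes do not match across samples."""


class EmptySampleError(MeripQCError):
    """A sample has zero reads where reads are required."""


class FilterError(MeripQCError):
    """No gene or bin survives a required filter."""


class DegenerateSignalError(MeripQCError):
    """The IP signal is identically zero."""


class InsufficientGenesError(MeripQCError):
    """Too few usable genes for a gene-level statistic."""


class GroupSizeError(MeripQCError):
    """A replicate group has fewer than two samples."""


class SimulationSpecError(MeripQCError):
    """A simulation specification is infeasible."""
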