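"""Exception hierarchy shared by all analysis stages."""


class DomainDynError(Exception):
    """Base class for all package errors."""


class ParseError(DomainDynError):
    """Malformed input file; the message names the offending line."""


class EmptyInputError(DomainDynError):
    """An input that must contain data was empty."""


class SelectionError(DomainDynError):
    """An atom selection resolved to nothing."""


class GroupDefinitionError(DomainDynError):
    """A named atom group could not be built; message lists missing atoms."""


class GeometryError(DomainDynError):
    """Degenerate geometry (zero-length vector, <3 points, collinear set)."""


class AlignmentError(DomainDynError):
    """Atom correspondence mismatch between two structures/trajectories."""


class DegenerateInputError(DomainDynError):
    """Input formally valid but degenerate for the requested statistic."""


class CoverageError(DomainDynError):
    """Force windows leave a gap along the reaction coordinate."""


class GridError(DomainDynError):
    """Overlapping force windows do not share a common bin grid."""


class UndefinedKappaError(DomainDynError):
    """Correlation length is undefined (zero-variance series)."""


class NoDataError(DomainDynError):
    """A span of the reaction coordinate contains no force samples."""


class ContextError(DomainDynError):
    """Invalid thermodynamic context (non-positive T or C)."""


class InputError(DomainDynError):
    """Generic invalid argument."""


class BasisError(DomainDynError):
    """Mode-set dimension mismatch."""


class NormalizationError(DomainDynError):
    """Zero frequencies present where a 1/omega weight is required."""


class DecompositionError(DomainDynError):
    """A residue carries no atoms of the requested policy."""


class FeasibilityError(DomainDynError):
    """A requested synthetic schedule cannot be realized geometrically."""


class SaddlePointWarning(UserWarning):
    """Hessian has negative curvature beyond the rigid-body tolerance."""


class ConnectivityWarning(UserWarning):
    """Elastic network has atoms without neighbors inside the cutoff."""
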