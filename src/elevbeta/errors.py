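"""Exception hierarchy used across the package."""


class ElevBetaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ElevBetaError, ValueError):
    """Invalid simulation or pipeline configuration."""


class EmptyAssemblageError(ElevBetaError, ValueError):
    """Pairwise dissimilarity requested for an empty assemblage."""


class HullInfeasible(ElevBetaError):
    """Too few species to span a convex hull in the requested dimensionality.

    Raised when an assemblage has fewer than ``n_axes + 1`` species; this is
    the condition under which an assemblage is dropped from the analysis.
    """


class HullDegenerate(ElevBetaError):
    """Species coordinates are affinely degenerate (hull volume below tolerance)."""


class NonEuclideanDistanceError(ElevBetaError):
    """Distance matrix has a substantial negative eigenvalue under classical scaling."""


class DegenerateSpaceError(ElevBetaError):
    """No positive eigenvalue survives the retention tolerance in PCoA."""
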