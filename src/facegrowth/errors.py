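"""Exception hierarchy.

Every error raised by this package derives from :class:`FaceGrowthError`,
so callers embedding the library can catch one base class.
"""


class FaceGrowthError(Exception):
    """Base class for all facegrowth errors."""


class ValidationError(FaceGrowthError, ValueError):
    """An input violates a documented contract (shapes, metadata, config)."""


class MeshFormatError(FaceGrowthError):
    """A mesh file could not be parsed or uses an unsupported layout."""


class CorrespondenceError(FaceGrowthError):
    """A mesh does not match the template topology (wrong vertex count)."""


class DegenerateGeometryError(FaceGrowthError):
    """Geometry too degenerate for the requested operation.

    Examples: all-coincident vertices, a rank-deficient point configuration
    (reflection ambiguity in Procrustes), or a vertex whose incident
    triangles all have zero area.
    """


class ConvergenceError(FaceGrowthError):
    """An iterative procedure did not converge within its iteration budget."""


class InsufficientDataError(FaceGrowthError):
    """Not enough training data to satisfy the requested effective sample size."""


class ExtrapolationError(FaceGrowthError):
    """A model was evaluated outside the training age range without opting in."""


class DegenerateDesignError(FaceGrowthError):
    """The (weighted) regression design has no age variance."""


class SingularProjectionError(FaceGrowthError):
    """The weighted projection onto shape-model modes is rank deficient."""


class InvalidModelError(FaceGrowthError):
    """A statistical shape model violates its invariants (e.g. variance <= 0)."""


class ArchiveIntegrityError(FaceGrowthError):
    """A model archive on disk is incomplete or internally inconsistent."""


class UnsupportedVersionError(FaceGrowthError):
    """A model archive was written with an unknown format version."""
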