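"""Exception hierarchy.

All package-specific failures derive from :class:`OssomechError` so callers
can catch one base class at pipeline level while per-stage code raises the
specific subclass.
"""


class OssomechError(Exception):
    """Base class for all ossomech errors."""


class ValidationError(OssomechError):
    """A model document, pose, or table violates its schema or invariants."""


class DegenerateInputError(OssomechError):
    """Geometric fit input is degenerate (too few, collinear, coplanar...)."""


class SingularPoseError(OssomechError):
    """Joint axes are (near-)parallel in the current pose: gimbal degeneracy."""


class InfeasibleAttachmentError(OssomechError):
    """A muscle attachment or via point lies strictly inside an obstacle."""


class ConvergenceError(OssomechError):
    """The wrapping fixed-point iteration failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EmptySweepError(OssomechError):
    """A moment-arm sweep produced no feasible cells to aggregate."""


class MeshError(OssomechError):
    """A surface mesh is unusable (open, empty...) for circumference measurement."""


class UndefinedCorrelationError(OssomechError):
    """Correlation requested on data with zero variance in the predictor."""


class SingularMatrixError(OssomechError):
    """The phylogenetic covariance matrix is singular."""
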