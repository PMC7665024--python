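"""Exception hierarchy for deerflex.

Every error raised by the library derives from :class:`DeerflexError`, so
callers batch-processing many traces can catch a single base class.
"""


class DeerflexError(Exception):
    """Base class for all deerflex errors."""


class InvalidGridError(DeerflexError):
    """Distance or time grid violates its invariants (non-uniform, out of range)."""


class GridMismatchError(DeerflexError):
    """Two objects that must share a grid do not."""


class InvalidParameterError(DeerflexError):
    """A physical parameter is outside its admissible range."""


class InsufficientTailError(DeerflexError):
    """Too few points in the background-fit window."""


class DegenerateModulationError(DeerflexError):
    """Modulation depth too small for background-corrected inversion."""


class PathIntegrityError(DeerflexError):
    """Regularization path violates its monotonicity invariants."""


class UndefinedModeError(DeerflexError):
    """Mode requested on an empty-solution distribution."""


class MissingReferenceError(DeerflexError):
    """Requested reference label absent from a result collection."""


class EmptyStructureError(DeerflexError):
    """PDB input contains no usable ATOM records."""


class PDBParseError(DeerflexError):
    """Malformed PDB record; carries the offending line number."""


class BuriedSiteError(DeerflexError):
    """No sterically allowed spin-label position at the requested site."""

    def __init__(self, message: str, n_attempts: int = 0):
        super().__init__(message)
        self.n_attempts = n_attempts


class GeometryError(DeerflexError):
    """Synthetic structure parameters produce overlapping geometry."""


class UndefinedEfficiencyError(DeerflexError):
    """FRET reference intensity is zero."""


class DegenerateNormalizationError(DeerflexError):
    """Release-assay controls coincide; fraction undefined."""


class InvalidReferenceError(DeerflexError):
    """Reference diffusion coefficient is non-positive."""


class FitFailureError(DeerflexError):
    """Nonlinear fit failed to converge; carries residual diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DeerflexWarning(UserWarning):
    """Base class for all deerflex warnings."""


class BoundaryTruncationWarning(DeerflexWarning):
    """Density does not fall below half maximum inside the grid; FWHM clamped."""


class OutOfGridWarning(DeerflexWarning):
    """Predicted pair distances fall outside the grid; mass clipped."""


class ConvergenceWarning(DeerflexWarning):
    """Iterative refinement stopped before reaching its target window."""
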