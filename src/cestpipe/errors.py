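"""Exception hierarchy for the CEST postprocessing pipeline.

Every guarded failure mode in the pipeline raises a subclass of
:class:`CestPipeError` so callers (and the CLI) can distinguish pipeline
errors from programming errors.
"""


class CestPipeError(Exception):
    """Base class for all pipeline errors."""


class DegenerateVoxelError(CestPipeError):
    """Zero or negative unsaturated reference intensity at a voxel."""


class InvalidInputError(CestPipeError):
    """Non-finite or otherwise malformed input data."""


class InsufficientDataError(CestPipeError):
    """Too few samples (offsets, TRs, subjects) for the requested operation."""


class NoDipError(CestPipeError):
    """WASSR spectrum has no identifiable water dip (flat spectrum)."""


class UnreliableShiftError(CestPipeError):
    """WASSR minimum sits at an axis endpoint or the shift is out of range."""


class InvalidParameterError(CestPipeError):
    """Nonphysical model parameter (e.g. nonpositive Lorentzian width)."""


class NonPhysicalFitError(CestPipeError):
    """Fit produced a nonphysical quantity (e.g. Z_lab <= 0)."""


class InvalidT1Error(CestPipeError):
    """Nonpositive or non-finite T1 passed to AREX."""


class IncompatibleMapsError(CestPipeError):
    """Map arithmetic attempted across mismatched grids or metrics."""


class UndefinedCNRError(CestPipeError):
    """CNR requested for two ROIs that both have zero variance."""


class EmptyROIError(CestPipeError):
    """ROI does not intersect the valid-voxel mask."""


class OutOfRangeError(CestPipeError):
    """Requested offset lies outside the acquired axis."""


class DesignError(CestPipeError):
    """Invalid synthetic-data design (e.g. overlapping phantom vials)."""


class CalibrationError(CestPipeError):
    """Requested cohort mean/SD unattainable by the amplitude response curve."""


class ConfigError(CestPipeError):
    """Invalid or incomplete pipeline configuration."""
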