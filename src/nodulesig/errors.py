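"""Exception hierarchy shared across the package."""


class NoduleSigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NoduleSigError):
    """Unrecognized or malformed file format."""


class ShapeError(NoduleSigError):
    """Payload does not have the expected dimensionality."""


class AlignmentError(NoduleSigError):
    """Volume and mask are not on the same voxel grid."""


class BoundsError(NoduleSigError):
    """Geometry extends outside the voxel grid."""


class SeedRejectedError(NoduleSigError):
    """Seed voxel attenuation falls outside the growing thresholds."""


class EmptyMaskError(NoduleSigError):
    """An operation produced or received an empty segmentation."""


class ReproducibilityError(NoduleSigError):
    """Replaying a segmentation session did not reproduce its stored result."""


class CapacityError(NoduleSigError):
    """Fewer eligible sampling sites than requested."""


class CalibrationError(NoduleSigError):
    """No preference value attains the requested exemplar count."""

    def __init__(self, message: str, nearest_below: int | None = None,
                 nearest_above: int | None = None):
        super().__init__(message)
        self.nearest_below = nearest_below
        self.nearest_above = nearest_above


class BalanceError(NoduleSigError):
    """Observer table is not a complete nodule-by-observer crossing."""


class UndefinedStatisticError(NoduleSigError):
    """The requested statistic is undefined for this input (e.g. zero variance)."""


class DegenerateDataError(NoduleSigError):
    """Data admit no meaningful test (e.g. all values identical)."""
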