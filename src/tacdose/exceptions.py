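"""Exception hierarchy.

All errors raised by the library derive from :class:`TacdoseError` so callers
can catch pipeline failures with a single ``except`` clause while programming
errors (``TypeError`` etc.) still propagate.
"""


class TacdoseError(Exception):
    """Base class for all tacdose errors."""


class InvalidParameterError(TacdoseError, ValueError):
    """Kinetic parameters violate a model invariant (caller bug, not data)."""


class DivergentIntegralError(TacdoseError, ValueError):
    """A clearance component has a non-positive rate; the TAC integral diverges."""


class InsufficientDataError(TacdoseError, ValueError):
    """Fewer samples than free parameters."""


class SinglePatientError(TacdoseError, ValueError):
    """Jackknife estimation needs at least two patients."""


class ModelMismatchError(TacdoseError, ValueError):
    """Operation requested for a model it is not defined for."""


class MixedPatientError(TacdoseError, ValueError):
    """VOIs from different patients passed where one patient is required."""


class NegativeDensityError(TacdoseError, ValueError):
    """HU-to-density calibration returned a non-positive density."""


class MissingTimePointError(TacdoseError, ValueError):
    """A sampling schedule requests a nominal day with no matching sample."""


class ZeroReferenceError(TacdoseError, ZeroDivisionError):
    """Relative deviation requested against a zero reference BED."""


class DegenerateVarianceError(TacdoseError, ValueError):
    """Correlation requested on data with zero variance."""


class AllModelsExcludedError(TacdoseError, RuntimeError):
    """Every candidate model failed the goodness-of-fit exclusion rules."""


class EmptyMaskError(TacdoseError, ValueError):
    """A segmentation produced or received an empty voxel mask."""


class OutOfGridError(TacdoseError, ValueError):
    """A requested VOI does not fit inside the image grid."""


class SphereOverlapError(TacdoseError, ValueError):
    """Synthetic phantom spheres overlap."""


class TacTableError(TacdoseError, ValueError):
    """Malformed time-activity CSV table."""


class ConfigError(TacdoseError, ValueError):
    """Malformed or unknown keys in a run configuration."""
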