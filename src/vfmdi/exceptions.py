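"""Exception hierarchy for the vfmdi toolkit.

Every error raised by the library derives from :class:`VfMdiError` so callers
can catch the whole family; subclasses distinguish contract violations
(parameters, schemas) from data problems (non-finite samples, degenerate
inputs) and evaluation problems (single-class metrics).
"""


class VfMdiError(Exception):
    """Base class for all vfmdi errors."""


class FormatError(VfMdiError):
    """A file could not be parsed in the declared format."""


class DataError(VfMdiError):
    """Input data violates an invariant (e.g. non-finite samples)."""


class BoundaryError(VfMdiError):
    """Requested window falls outside the available signal."""


class ParameterError(VfMdiError):
    """An operation parameter violates its precondition."""


class SchemaError(VfMdiError):
    """A feature table violates the expected schema."""


class DegenerateInputError(VfMdiError):
    """Input carries no usable structure (constant signal, zero diameter)."""


class DegenerateVarianceError(VfMdiError):
    """Both variance terms of the sep denominator fall below the floor."""


class GridError(VfMdiError):
    """Two densities are not defined on a common grid."""


class ConfigError(VfMdiError):
    """Configuration mismatch (parameterization, schema of a fitted model)."""


class EvaluationError(VfMdiError):
    """A metric is undefined for the given inputs (e.g. one class only)."""


class StratificationError(VfMdiError):
    """Cross-validation folds cannot contain both classes."""


class SelectionError(VfMdiError):
    """Parameter selection failed at every grid point."""


class ScalingError(VfMdiError):
    """Standardization impossible (constant feature column)."""


class RankError(VfMdiError):
    """A covariance matrix required to be full rank is singular."""


class EmptyDensityError(VfMdiError):
    """A quasi-period histogram was requested for an empty sample."""
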