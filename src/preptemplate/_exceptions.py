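"""Exception hierarchy.

Everything raised by this package derives from :class:`PrepTemplateError`,
so callers can catch one type at pipeline boundaries.  Most subclasses also
derive from ``ValueError`` so that generic input validation idioms keep
working.
"""


class PrepTemplateError(Exception):
    """Base class for all package errors."""


class ParameterError(PrepTemplateError, ValueError):
    """A scalar parameter is outside its documented domain."""


class InvalidDesignError(PrepTemplateError, ValueError):
    """A task design request violates the trial-count constraints."""


class ShapeError(PrepTemplateError, ValueError):
    """Mismatched array shapes, voxel counts, or TRs."""


class DegenerateVoxelError(PrepTemplateError, ValueError):
    """A voxel's run mean is non-positive, so percent signal change is undefined."""


class EmptySelectionError(PrepTemplateError, ValueError):
    """A selection step retained nothing (voxels or trials)."""


class SelectionError(PrepTemplateError, ValueError):
    """Invalid voxel-selection request (e.g. k larger than available)."""


class LabelingError(PrepTemplateError, ValueError):
    """A trial could not be mapped onto an FIR regressor label."""


class DesignMatrixError(PrepTemplateError, ValueError):
    """An event falls outside the modeled time range."""


class ConditioningError(PrepTemplateError, ValueError):
    """A covariance matrix is singular; increase the shrinkage."""


class MappingError(PrepTemplateError, ValueError):
    """Missing label correspondence between train and test sets."""


class InsufficientDataError(PrepTemplateError, ValueError):
    """Too few trials per class to fit a classifier."""


class DegenerateDataError(PrepTemplateError, ValueError):
    """Zero-variance input where a test statistic needs spread."""


class UndefinedBSIError(PrepTemplateError, ValueError):
    """Stimulus-period peak is non-positive, the BSI ratio is undefined."""


class BalancedDesignError(PrepTemplateError, ValueError):
    """Repeated-measures ANOVA requires a fully crossed design."""


class DegenerateGroupingError(PrepTemplateError, ValueError):
    """A quadrant grouping left some quadrant without voxels."""


class WindowError(PrepTemplateError, IndexError):
    """An averaging window falls outside the available bins."""


class PipelineStageError(PrepTemplateError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
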