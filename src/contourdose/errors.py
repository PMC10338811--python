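"""Exception hierarchy.

Every error raised by this package derives from :class:`ContourDoseError`
so callers can catch the whole family; specific subclasses mirror the
failure modes of the pipeline (geometry mismatches, invalid masks,
metrics that are undefined on degenerate input, ...).
"""


class ContourDoseError(Exception):
    """Base class for all contourdose errors."""


class GeometryError(ContourDoseError):
    """Two voxel grids that must match do not (dims, spacing or origin)."""


class ValidationError(ContourDoseError):
    """A data object violates its contract (non-binary mask, missing ROI...)."""


class CaseIOError(ContourDoseError, OSError):
    """A case manifest or one of its volumes could not be read or written."""


class UndefinedMetricError(ContourDoseError):
    """A geometric or dosimetric metric is undefined on this input
    (e.g. both masks empty, D95 = 0)."""


class UndefinedStatisticError(ContourDoseError):
    """A statistic is undefined (zero rank variance, all-zero differences,
    too few samples)."""


class GenerationError(ContourDoseError):
    """The synthetic-data generator produced an invalid object
    (organ colliding with the target, perturbation emptied a mask)."""


class NormalizationError(UndefinedMetricError):
    """Plan normalization impossible (target D95 is zero)."""


class SchemaError(ContourDoseError):
    """A cohort table is missing a requested metric column."""
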