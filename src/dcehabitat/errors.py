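"""Exception hierarchy for the habitat-radiomics pipeline."""


class DCEHabitatError(Exception):
    """Base class for all package errors."""


class DomainError(DCEHabitatError, ValueError):
    """A scalar argument is outside its documented domain."""


class GeometryError(DCEHabitatError, ValueError):
    """A simulated lesion does not fit the requested image geometry."""


class CohortError(DCEHabitatError, ValueError):
    """A cohort request is degenerate (e.g. a single-class cohort)."""


class DimensionError(DCEHabitatError, ValueError):
    """Array shapes are incompatible."""


class DegenerateClusterError(DCEHabitatError, ValueError):
    """Clustering cannot proceed (constant image, coincident centers)."""


class TooSmallLesionError(DCEHabitatError, ValueError):
    """A refined lesion mask fell below the minimum pixel count."""


class EmptyRegionError(DCEHabitatError, ValueError):
    """An operation received an empty mask or label map."""


class EmptyMatrixError(DCEHabitatError, ValueError):
    """No valid pixel pairs exist for a co-occurrence offset."""


class EmptyTableError(DCEHabitatError, ValueError):
    """A feature-table filter removed every column."""


class ExpectedCountError(DCEHabitatError, ValueError):
    """Chi-square expected counts below 5; Fisher's exact test required."""
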