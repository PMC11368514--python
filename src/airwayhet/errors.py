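"""Exception hierarchy.

All package errors derive from :class:`AirwayHetError` so callers can catch
validation problems (exit code 2 in the CLI) separately from runtime faults.
"""


class AirwayHetError(Exception):
    """Base class for all package errors."""


class SiteVocabularyError(AirwayHetError):
    """An airway-site label outside the closed 19-site vocabulary."""


class KnotSpecError(AirwayHetError):
    """Invalid spline knot specification (too few, unordered, non-finite x)."""


class CellSizeError(AirwayHetError):
    """A (sex, site) normative cell below the minimum fitting sample size."""


class RankDeficiencyError(AirwayHetError):
    """Rank-deficient reference-model design; fewer knots may help."""


class MissingCovariateError(AirwayHetError):
    """A required covariate (sex, age, height, tlv) is missing."""


class ProfileError(AirwayHetError):
    """Invalid percent-predicted profile (bad diameter, empty profile)."""


class InsufficientSitesError(AirwayHetError):
    """Fewer non-missing sites than the summary requires."""


class DegenerateExposureError(AirwayHetError):
    """Zero-variance or all-identical exposure where spread is required."""


class UndefinedCorrelationError(AirwayHetError):
    """Correlation undefined because one input vector is constant."""


class SeparationError(AirwayHetError):
    """Complete or quasi-complete separation in a logistic fit."""


class CollinearityError(AirwayHetError):
    """Aliased (collinear) terms in a regression design."""


class ConfigError(AirwayHetError):
    """Invalid simulation or pipeline configuration; message lists fields."""


class SchemaError(AirwayHetError):
    """Input table violates the documented CSV schema."""


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the normative covariate envelope."""
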