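"""Exception hierarchy shared across the pipeline stages."""


class LingbrainError(Exception):
    """Base class for all package errors."""


# --- text / linguistic features ---------------------------------------------

class EmptyTranscript(LingbrainError):
    """No sentence with at least one token survives segmentation."""


class VocabularyTooSmall(LingbrainError):
    """Corpus vocabulary has fewer distinct tokens than the requested dimension."""


class AllPairsSkipped(LingbrainError):
    """Every consecutive sentence pair had a zero vector; no coherence defined."""


class TaggerUnavailable(LingbrainError):
    """No tagger available for the configured tagset."""


class InconsistentFeatureSets(LingbrainError):
    """Subjects carry different feature name sets."""


class DuplicateSubject(LingbrainError):
    """The same subject id appears more than once."""


class InsufficientSubjects(LingbrainError):
    """Fewer subjects than the operation requires."""


class AllFeaturesDropped(LingbrainError):
    """The degenerate-feature filter removed every column."""


# --- brain features ----------------------------------------------------------

class DomainError(LingbrainError):
    """Numeric input outside the mathematically valid domain."""


class ZeroVarianceNode(LingbrainError):
    """A node's time series is constant; correlation undefined."""


class ZeroVarianceMean(LingbrainError):
    """A network's averaged time series is constant."""


class SchemaViolation(LingbrainError):
    """Morphometry table does not match the expected feature schema."""


class NonPositiveValue(LingbrainError):
    """Thickness/volume value that must be positive is not."""


class AtlasError(LingbrainError):
    """Network atlas violates its invariants."""


# --- harmonization -----------------------------------------------------------

class SingularDesign(LingbrainError):
    """Design matrix (intercept + batch + covariates) is rank deficient."""


class TooFewPerBatch(LingbrainError):
    """A batch has fewer subjects than required for fitting."""


class ConstantFeature(LingbrainError):
    """A feature is constant in the pooled sample."""


class UnseenBatch(LingbrainError):
    """Transform called with a batch label absent at fit time."""


class FeatureMismatch(LingbrainError):
    """Transform called with a different feature set than at fit time."""


# --- sCCA --------------------------------------------------------------------

class ConstantColumn(LingbrainError):
    """Column with zero sample variance cannot be z-scored."""


class ZstateError(LingbrainError):
    """Operation applied to a block in the wrong raw/z-scored state."""


class NegativeLambda(LingbrainError):
    """Soft-threshold parameter must be non-negative."""


class ZeroVector(LingbrainError):
    """Projection of the zero vector is undefined."""


class BudgetOutOfRange(LingbrainError):
    """L1 budget outside [1, sqrt(dim)]."""


class NotZscored(LingbrainError):
    """sCCA requires z-scored blocks."""


class EmptyGrid(LingbrainError):
    """Sparsity grid contains no points."""


class TooFewPermutations(LingbrainError):
    """Permutation count below the minimum for reported inference."""


class AlignmentError(LingbrainError):
    """Subject ids/order do not align across data sources."""


# --- synthetic data / pipeline ----------------------------------------------

class InvalidSettings(LingbrainError):
    """Generator settings violate their constraints."""


class DimensionError(LingbrainError):
    """Planted supports or shapes inconsistent with requested dimensions."""


class InvalidCorrelationSpec(LingbrainError):
    """Requested correlation structure is not realizable."""


class ConfigError(LingbrainError):
    """Study configuration invalid or incomplete."""
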