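"""Exception hierarchy for the fhresponse package."""


class FHResponseError(Exception):
    """Base class for all package-specific errors."""


class UnmappedAgentError(FHResponseError, KeyError):
    """Statin agent (or agent/dose pair) absent from the equivalence table."""


class UnmappedRegimenError(FHResponseError, KeyError):
    """Regimen cannot be resolved to an expected-reduction entry."""


class NotApplicableError(FHResponseError, ValueError):
    """Operation requested for a regimen component that is not present."""


class InvalidBaselineError(FHResponseError, ValueError):
    """Pre-treatment LDL-C is zero, negative, or non-finite."""


class InvalidExpectationError(FHResponseError, ValueError):
    """Expected reduction E must be a positive percentage."""


class HGVSParseError(FHResponseError, ValueError):
    """Variant notation could not be parsed; carries the offending text."""


class ClassificationInputError(FHResponseError, ValueError):
    """Variant record is missing fields needed for null/defective assignment."""


class UnsupportedGenotypeError(FHResponseError, ValueError):
    """Patient carries more pathogenic alleles than the grouping supports."""


class EmptyGenotypeError(FHResponseError, ValueError):
    """All SNP dosages are missing for a patient."""


class WeightMismatchError(FHResponseError, KeyError):
    """Genotype rsIDs do not match the weight set."""


class DegenerateWeightError(FHResponseError, ValueError):
    """A SNP weight has beta == 0 and cannot be oriented."""


class EmptyInputError(FHResponseError, ValueError):
    """A statistical operation received an empty sample."""


class DegeneratePredictorError(FHResponseError, ValueError):
    """Regression predictor is constant."""


class DegenerateTableError(FHResponseError, ValueError):
    """Contingency table has an all-zero row or column margin."""


class ConfigValidationError(FHResponseError, ValueError):
    """Simulation or run configuration violates its invariants."""
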