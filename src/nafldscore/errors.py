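"""Exception hierarchy for cohort validation and model fitting."""


class NafldScoreError(Exception):
    """Base class for all package errors."""


class CohortFormatError(NafldScoreError):
    """Malformed cohort table or VCF (missing columns, bad dialect, non-diploid GT)."""


class GenotypeValidationError(NafldScoreError):
    """A genotype string is not composed of the SNP's two alleles."""


class PanelLookupError(NafldScoreError):
    """A panel SNP could not be found in an input file."""


class DegenerateInputError(NafldScoreError):
    """Statistical input is degenerate (empty group, zero margin, empty counts)."""


class SeparationError(NafldScoreError):
    """Complete or quasi-complete separation: the logistic MLE does not exist."""


class RankDeficiencyError(NafldScoreError):
    """The design matrix is rank deficient; coefficients are not identifiable."""


class ConvergenceError(NafldScoreError):
    """Iteratively reweighted least squares failed to converge."""
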