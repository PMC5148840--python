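"""Exception and warning types shared across the pipeline."""


class OgttoolsError(Exception):
    """Base class for all package-specific errors."""


class MissingDataError(OgttoolsError):
    """A required measurement is absent for a subject."""

    def __init__(self, subject_id, what):
        self.subject_id = subject_id
        self.what = what
        super().__init__(f"subject {subject_id!r}: missing {what}")


class DomainError(OgttoolsError, ValueError):
    """An input value lies outside the mathematical domain of an index."""


class DegenerateReferenceError(OgttoolsError):
    """The reference sample cannot support tertile boundaries."""


class RankDeficiencyError(OgttoolsError):
    """The regression design matrix is rank deficient."""

    def __init__(self, terms):
        self.terms = list(terms)
        super().__init__(f"design matrix rank deficient; collinear terms: {self.terms}")


class NonIdentifiableError(OgttoolsError):
    """The comparison group's slope is too close to zero to solve for a cut-off."""


class ConvergenceError(OgttoolsError):
    """An iterative fit (logistic regression) failed to converge."""


class SchemaError(OgttoolsError):
    """A cohort file does not conform to the declared schema."""


class ExtrapolationWarning(UserWarning):
    """A solved cut-off lies outside the comparison group's observed range."""


class CollinearityWarning(UserWarning):
    """A variance inflation factor reached the acceptance bound."""


class AgeAdjustmentWarning(UserWarning):
    """Age adjustment was skipped (zero age variance)."""
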