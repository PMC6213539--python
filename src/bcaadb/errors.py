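"""Exception hierarchy for bcaadb."""


class BcaadbError(Exception):
    """Base class for all package errors."""


class InvalidFactorError(BcaadbError):
    """Nitrogen-to-protein conversion factor is non-positive."""


class DivisionUndefinedError(BcaadbError):
    """Reference has amino acids but no nitrogen — the adjustment ratio is undefined."""


class ToleranceViolationError(BcaadbError):
    """Explicit reference mapping outside the protein tolerance."""


class MissingReferenceValuesError(BcaadbError):
    """Reference item carries no amino-acid values."""


class UnresolvedIngredientError(BcaadbError):
    """Recipe ingredient missing from the table or not compiled."""


class NotEligibleError(BcaadbError):
    """Zero-content assignment requested for a protein-containing item."""


class UncompiledItemError(BcaadbError):
    """A recall record references an item without compiled amino-acid values."""


class UnknownItemError(BcaadbError):
    """A recall record references an item id absent from the food table."""


class ValidationError(BcaadbError):
    """Invalid input values (anthropometrics, questionnaire answers, ...)."""


class DegenerateBreaksError(BcaadbError):
    """Too few distinct nonzero values to compute category breaks."""


class SeparationError(BcaadbError):
    """Complete separation in the logistic fit; consider a penalized fallback."""


class DegenerateOutcomeError(BcaadbError):
    """Outcome constant — association model cannot be fit."""


class UndefinedContributionError(BcaadbError):
    """Population total intake is zero; contributions undefined."""


class SchemaError(BcaadbError):
    """CSV header does not satisfy the declared schema."""
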