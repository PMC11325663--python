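"""Exception hierarchy for the dairy-disaggregation pipeline.

Every validation failure raises a distinct, named exception so that callers
(and the CLI) can report precisely what is wrong with an input file rather
than surfacing a generic ``ValueError``.
"""


class DairyDisaggError(Exception):
    """Base class for all package errors."""


class SchemaError(DairyDisaggError):
    """An input table is missing required columns or has malformed values."""


class DuplicateEntryError(DairyDisaggError):
    """A (parent, component) recipe pair or an ingredient code occurs twice."""


class RecipeCycleError(DairyDisaggError):
    """The recipe graph contains a cycle; names the codes involved."""

    def __init__(self, codes):
        self.codes = tuple(codes)
        super().__init__(f"recipe graph contains a cycle involving: {', '.join(self.codes)}")


class UnresolvableFoodError(DairyDisaggError):
    """A food code is neither in the database nor covered by a substitution."""


class UnclassifiedIngredientError(DairyDisaggError):
    """A base ingredient is in neither the dairy nor the non-dairy roster."""


class EmptyInputError(DairyDisaggError):
    """An operation that needs at least one record received none."""


class UndefinedBiasError(DairyDisaggError):
    """Percent bias requested with a zero denominator and nonzero numerator."""


class MissingFactorError(DairyDisaggError):
    """A consumed dairy category has no milk-equivalence factor."""


class InvalidClassError(DairyDisaggError):
    """A dairy classification violates category/fat-level/variety compatibility."""


class GeneratorConfigError(DairyDisaggError):
    """A synthetic-data configuration is infeasible or inconsistent."""
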