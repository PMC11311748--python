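"""Exception hierarchy shared across the package."""


class FormulanetError(Exception):
    """Base class for all package errors."""


class CorpusFormatError(FormulanetError):
    """Input table is structurally malformed (missing columns, bad header)."""


class CorpusConsistencyError(FormulanetError):
    """A token is used with conflicting kinds, or references are dangling."""


class CorpusValidationError(FormulanetError):
    """A corpus-level invariant is violated (e.g. a prescription with no herbs)."""


class EmptyInputError(FormulanetError):
    """An operation received an empty corpus, member set, or matrix."""


class UndefinedSimilarityError(FormulanetError):
    """Jaccard similarity of two empty sets (0/0) was requested."""


class ParameterError(FormulanetError):
    """An out-of-range or mutually inconsistent parameter was supplied."""


class ValidityError(FormulanetError):
    """A validity statistic is undefined for the given assignment (e.g. k < 2)."""


class SyntheticSpecError(FormulanetError):
    """A synthetic corpus specification is infeasible or inconsistent."""


class ConfigError(FormulanetError):
    """A pipeline configuration is invalid."""


class StageError(FormulanetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
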