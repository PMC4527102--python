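"""Exception hierarchy for spcdiff."""


class SpcdiffError(Exception):
    """Base class for all spcdiff errors."""


class FormatError(SpcdiffError):
    """A file does not conform to the expected TSV dialect."""


class ValidationError(SpcdiffError):
    """Data violates an invariant (negative count, duplicate id, ...)."""


class ReconciliationError(SpcdiffError):
    """Counts file and design file disagree about the column set."""


class DesignError(SpcdiffError):
    """The group design is unusable (wrong number of groups, bad labels)."""


class ParameterError(SpcdiffError):
    """A parameter is outside its admissible range."""


class DegenerateTableError(SpcdiffError):
    """A 2x2 contingency table has a zero margin; the test is undefined."""


class UndefinedInputError(SpcdiffError):
    """A statistic was requested for an input on which it is undefined."""


class InconsistentSummaryError(SpcdiffError):
    """A protein's pooled counts exceed its group totals."""
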