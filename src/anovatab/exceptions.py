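"""Exception hierarchy shared across the package."""


class AnovatabError(Exception):
    """Base class for all errors raised by anovatab."""


class InputError(AnovatabError):
    """Unreadable, empty or otherwise invalid user input."""


class SchemaError(InputError):
    """The table's columns do not form a two-factor long-format dataset."""


class SheetNotFoundError(AnovatabError, LookupError):
    """A requested worksheet does not exist in the workbook."""


class DesignError(AnovatabError):
    """The factorial design is degenerate (constant factor, empty cell, ...)."""


class ReplicationError(DesignError):
    """Exactly one observation per treatment: two-way ANOVA with interaction
    cannot be conducted, and no table is generated for the sheet."""


class NumericError(AnovatabError):
    """A computation is undefined for the data (zero residual df, MSE = 0)."""
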