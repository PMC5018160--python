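"""Exception hierarchy shared by all matriline modules."""


class MatrilineError(Exception):
    """Base class for all package errors."""


class PedigreeFormatError(MatrilineError):
    """The input file violates the pedigree CSV dialect (bad header, short row, duplicate id ...)."""


class FatalPedigreeError(MatrilineError):
    """The pedigree contains fatal structural errors (ancestry cycles, parental-role
    gender inconsistencies) that must be fixed before any analysis."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__(
            "fatal pedigree errors: " + "; ".join(e.message for e in self.errors)
        )


class ConflictError(MatrilineError):
    """Haplotype conflicts exist in maternal lines; imputation and effective-size
    calculations refuse to run. Run the verification step first."""


class UndefinedResultError(MatrilineError):
    """A requested quantity is mathematically undefined for this input
    (e.g. no females in the reference population)."""


class ConfigError(MatrilineError):
    """Invalid configuration or impossible request (bad budget, impossible synthetic setup ...)."""
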