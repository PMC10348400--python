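"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation errors -> 2, data errors -> 3,
anything else -> 4.
"""


class ChemSimNetError(Exception):
    """Base class for all package errors."""


class ValidationError(ChemSimNetError):
    """A parameter or configuration value is outside its documented range."""


class SchemaError(ChemSimNetError):
    """An input table is missing required columns or has malformed cells."""


class SmilesParseError(ChemSimNetError):
    """A SMILES string could not be parsed.

    Carries the offending string in ``smiles``.
    """

    def __init__(self, smiles: str, message: str | None = None):
        self.smiles = smiles
        super().__init__(message or f"unparseable SMILES: {smiles!r}")


class DataError(ChemSimNetError):
    """Input data is structurally valid but unusable (empty, degenerate...)."""
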