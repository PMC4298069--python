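"""Exception hierarchy.

All package errors derive from :class:`SkinsensError` so callers (and the
CLI, which maps them to exit code 3) can catch one base class.
"""


class SkinsensError(Exception):
    """Base class for all skinsens errors."""


class SchemaError(SkinsensError):
    """A table is missing a mandatory column or uses an unknown schema."""


class RowParseError(SkinsensError):
    """A data row holds an unparseable value; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class StructureError(SkinsensError):
    """A SMILES/structure string could not be parsed."""


class RuleError(SkinsensError):
    """A substructure alert pattern failed to compile."""


class DescriptorParseError(SkinsensError):
    """A quantum-chemistry output log lacks a required block."""


class DegenerateDescriptorError(SkinsensError):
    """A descriptor is constant on the fitting data (min == max)."""


class NotFittedError(SkinsensError):
    """Normalization parameters or a model were used before fitting."""


class SingularDesignError(SkinsensError):
    """The regression design matrix is rank deficient."""


class CalibrationError(SkinsensError):
    """Anchor rows are mutually inconsistent under the fixed slope."""


class LengthMismatchError(SkinsensError):
    """Two aligned sequences differ in length."""
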