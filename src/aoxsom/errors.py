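"""Exception hierarchy.

Three broad families, mirrored by the CLI exit codes: input errors
(unparseable or malformed user data), configuration errors (bad specs,
recipes, or model/featurizer mismatches), and numeric/degenerate errors
(computations whose preconditions a dataset fails to meet).
"""


class AoxsomError(Exception):
    """Base class for all package errors."""


# --- input errors -----------------------------------------------------------

class InputError(AoxsomError):
    """Malformed or unreadable user input."""


class EmptyInputError(InputError):
    pass


class SmilesParseError(InputError):
    def __init__(self, smiles: str, context: str = ""):
        self.smiles = smiles
        msg = f"cannot parse SMILES: {smiles!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class ReactionFormatError(InputError):
    """Reaction SMILES without exactly one '>>' separator, or unparseable sides."""


class AtomMapIntegrityError(InputError):
    """A nonzero atom-map number occurs more than once on one side."""


class TokenizationError(InputError):
    def __init__(self, smiles: str, position: int):
        self.smiles = smiles
        self.position = position
        super().__init__(
            f"unrecognized character {smiles[position]!r} at position {position} in {smiles!r}"
        )


class LabelExtractionError(InputError):
    """Reaction not atom-mapped, or labels inconsistent with the substrate."""


class SchemaError(InputError):
    """Dataset file whose columns/properties cannot be recognized."""


# --- configuration errors ---------------------------------------------------

class ConfigError(AoxsomError):
    pass


class FingerprintSpecError(ConfigError):
    """Ill-formed fingerprint recipe (bad family, radius, or width)."""


class MoleculeStateError(ConfigError):
    """Operation requires a standardized molecule with perceived aromaticity."""


class ReferenceMismatchError(ConfigError):
    """Two objects that must refer to the same molecule do not."""


class ModelArchiveError(ConfigError):
    """Corrupt or version-incompatible persisted model."""


# --- numeric / degenerate errors -------------------------------------------

class NumericError(AoxsomError):
    pass


class DegenerateSelectionError(NumericError):
    """Feature selection would remove every column."""


class ScoringError(NumericError):
    """Univariate scoring impossible (e.g. single-class labels)."""


class DimensionError(NumericError):
    """Requested dimensionality exceeds what the data supports."""


class StratificationError(NumericError):
    """Cross-validation folds cannot all contain both classes."""


class UndefinedMetricError(NumericError):
    """Metric undefined for this input (e.g. AUC with a single class)."""


class FixtureGenerationError(NumericError):
    """Synthetic-substrate generation exhausted its retry budget."""
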