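"""Exception hierarchy shared across the package."""


class FragbayesError(Exception):
    """Base class for package errors."""


class SmilesParseError(FragbayesError, ValueError):
    """Raised when a SMILES string cannot be parsed.

    Attributes
    ----------
    position : int or None
        Best-effort index of the offending token in the input string, or
        ``None`` when the failure is structural (e.g. a valence violation)
        rather than lexical.
    """

    def __init__(self, smiles: str, position=None, reason: str = ""):
        self.smiles = smiles
        self.position = position
        where = f" (offending token at position {position})" if position is not None else ""
        detail = f": {reason}" if reason else ""
        super().__init__(f"cannot parse SMILES {smiles!r}{where}{detail}")


class EmptyLibraryError(FragbayesError, ValueError):
    """Raised when a compound library yields zero parseable records."""


class ParameterError(FragbayesError, ValueError):
    """Raised for out-of-range or inconsistent user parameters."""


class FitError(FragbayesError, ValueError):
    """Raised when a model cannot be fitted (e.g. single-class input)."""


class ConfigMismatchError(FragbayesError, ValueError):
    """Raised when a model and a feature configuration disagree."""
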