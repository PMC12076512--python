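"""Exception hierarchy shared across the package."""


class ProfisError(Exception):
    """Base class for all package-specific errors."""


class InvalidMoleculeError(ProfisError):
    """Raised when an input string cannot be parsed into a valid molecule."""

    def __init__(self, raw: str, reason: str = "unparseable SMILES"):
        self.raw = raw
        super().__init__(f"invalid molecule {raw!r}: {reason}")


class IncompatibleFingerprintsError(ProfisError):
    """Fingerprints of different type or length cannot be compared."""


class OutOfVocabularyError(ProfisError):
    """A string contains a token absent from the vocabulary."""

    def __init__(self, token: str, position: int):
        self.token = token
        self.position = position
        super().__init__(f"unknown token {token!r} at position {position}")


class TooLongError(ProfisError):
    """Tokenized sequence does not fit in the fixed sequence length."""


class UnconvertibleError(ProfisError):
    """Notation conversion failed for a given string."""


class ShapeError(ProfisError):
    """An array argument has the wrong dimensionality."""


class NotReadyError(ProfisError):
    """Model used before weights were initialized or loaded."""


class DegenerateFoldError(ProfisError):
    """A cross-validation fold contains a single class."""


class InfeasibleSpecError(ProfisError):
    """A fixture specification cannot produce molecules in the requested range."""
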