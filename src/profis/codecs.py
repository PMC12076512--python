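"""Tokenization, integer encoding, notation conversion and validity
accounting for the three sequential molecular notations.

Sequences are fixed-length (``SEQ_LEN`` = 100): structure tokens, then an
end marker, then padding.  A start token exists in every vocabulary for
decoder conditioning but is never stored in a :class:`TokenSequence`; the
model prepends it at teacher-forcing/decoding time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .errors import OutOfVocabularyError, TooLongError, UnconvertibleError
from .notation import deepsmiles as _ds
from .notation import selfies as _sf

SMILES = "smiles"
DEEPSMILES = "deepsmiles"
SELFIES = "selfies"
NOTATIONS = (SMILES, DEEPSMILES, SELFIES)

SEQ_LEN = 100
PAD, START, END = "<pad>", "<start>", "<end>"

_SMILES_LEX = re.compile(r"(\[[^\]]+\]|Cl|Br|%\d{2}|[BCNOPSFIbcnops]|[=#\-~/\\()]|\d)")
_DEEP_LEX = re.compile(r"(\[[^\]]+\]|Cl|Br|%\d{2}|[BCNOPSFIbcnops]|[=#\-~/\\)]|\d)")


def lex(s: str, notation: str) -> list[str]:
    """Greedy longest-match tokenization of a string in a given notation."""
    if notation == SELFIES:
        return _sf.split_tokens(s)
    pattern = _SMILES_LEX if notation == SMILES else _DEEP_LEX
    tokens, pos = [], 0
    while pos < len(s):
        m = pattern.match(s, pos)
        if not m:
            raise OutOfVocabularyError(s[pos], pos)
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


@dataclass
class TokenVocabulary:
    """Ordered token inventory for one notation, with special markers.

    Index layout: ``<pad>`` = 0, ``<start>`` = 1, ``<end>`` = 2, structure
    tokens from 3 upward in listed order.
    """

    notation: str
    tokens: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self._index = {t: i + 3 for i, t in enumerate(self.tokens)}

    pad_idx, start_idx, end_idx = 0, 1, 2

    @property
    def size(self) -> int:
        return len(self.tokens) + 3

    @property
    def n_structure_tokens(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        return self._index[token]

    def token(self, idx: int) -> str:
        if idx < 3:
            return (PAD, START, END)[idx]
        return self.tokens[idx - 3]


@dataclass
class TokenSequence:
    """Fixed-length integer-encoded token sequence."""

    indices: np.ndarray
    notation: str

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.shape != (SEQ_LEN,):
            raise ValueError(f"sequence must have length {SEQ_LEN}")


def build_vocabulary(corpus: Iterable[str], notation: str) -> TokenVocabulary:
    """Collect the sorted set of structure tokens appearing in a corpus."""
    seen: set[str] = set()
    for s in corpus:
        seen.update(lex(s, notation))
    return TokenVocabulary(notation, sorted(seen))


def tokenize(s: str, vocab: TokenVocabulary) -> TokenSequence:
    """Encode a string as indices padded to length 100.

    Layout: structure tokens, end marker, padding.  Raises
    :class:`~profis.errors.OutOfVocabularyError` for unknown tokens and
    :class:`~profis.errors.TooLongError` when tokens + end marker exceed
    the fixed length.
    """
    tokens = lex(s, vocab.notation)
    if len(tokens) + 1 > SEQ_LEN:
        raise TooLongError(f"{len(tokens)} tokens exceed sequence length {SEQ_LEN}")
    out = np.zeros(SEQ_LEN, dtype=np.int64)
    for i, tok in enumerate(tokens):
        if tok not in vocab._index:
            raise OutOfVocabularyError(tok, i)
        out[i] = vocab.index(tok)
    out[len(tokens)] = vocab.end_idx
    return TokenSequence(out, vocab.notation)


def detokenize(seq: TokenSequence | np.ndarray, vocab: TokenVocabulary) -> str:
    """Inverse of :func:`tokenize`; stops at the end marker."""
    indices = seq.indices if isinstance(seq, TokenSequence) else np.asarray(seq)
    parts = []
    for idx in indices:
        if idx in (vocab.end_idx, vocab.pad_idx):
            break
        if idx == vocab.start_idx:
            continue
        parts.append(vocab.token(int(idx)))
    return "".join(parts)


def convert_notation(smiles: str, target: str) -> str:
    """Convert a canonical SMILES string into the target notation."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnconvertibleError(f"unparseable SMILES {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    if target == SMILES:
        return canonical
    if target == DEEPSMILES:
        return _ds.encode(canonical)
    if target == SELFIES:
        return _sf.encode(canonical)
    raise ValueError(f"unknown notation {target!r}")


def to_smiles(s: str, notation: str) -> str:
    """Decode a string in any notation to canonical SMILES (raising
    :class:`~profis.errors.UnconvertibleError` when invalid)."""
    if notation == SMILES:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise UnconvertibleError(f"invalid SMILES {s!r}")
        return Chem.MolToSmiles(mol)
    if notation == DEEPSMILES:
        return _ds.decode(s)
    if notation == SELFIES:
        return _sf.decode(s)
    raise ValueError(f"unknown notation {notation!r}")


def validity_rate(strings: Sequence[str], notation: str) -> float:
    """Fraction of strings decoding to a valence-valid molecule."""
    if len(strings) == 0:
        raise ValueError("validity rate of an empty list is undefined")
    ok = 0
    for s in strings:
        try:
            to_smiles(s, notation)
            ok += 1
        except Exception:
            pass
    return ok / len(strings)


def random_selfies_sequences(
    n: int, seed: int, min_len: int = 8, max_len: int = 60
) -> list[str]:
    """Uniformly random token sequences over the total notation alphabet."""
    rng = np.random.default_rng(seed)
    alpha = _sf.ALPHABET
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append("".join(alpha[j] for j in rng.integers(0, len(alpha), length)))
    return out


# ---------------------------------------------------------------------------
# vocabulary files

def save_vocabulary(vocab: TokenVocabulary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# notation: {vocab.notation}\n")
        fh.write(f"# specials: {PAD} {START} {END}\n")
        for tok in vocab.tokens:
            fh.write(tok + "\n")


def load_vocabulary(path: str | Path) -> TokenVocabulary:
    notation = None
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# notation:"):
                notation = line.split(":", 1)[1].strip()
            elif line.startswith("# ") or not line:  # "#" alone is a bond token
                continue
            else:
                tokens.append(line)
    if notation not in NOTATIONS:
        raise ValueError(f"vocabulary file lacks a valid notation header")
    return TokenVocabulary(notation, tokens)


def reference_vocabulary(notation: str) -> TokenVocabulary:
    """The packaged reference vocabulary for a notation (29 SMILES, 28
    SELFIES and 46 DeepSMILES structure tokens)."""
    if notation not in NOTATIONS:
        raise ValueError(f"unknown notation {notation!r}")
    ref = resources.files("profis.data").joinpath(f"vocab_{notation}.txt")
    with resources.as_file(ref) as path:
        return load_vocabulary(path)
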