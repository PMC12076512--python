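"""Binary molecular fingerprints: folded circular ECFP4 and the key-based
KRFP-dimensional fingerprint, plus Tanimoto distance and bit-flip noising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem import MoleculeRecord
from .errors import IncompatibleFingerprintsError, InvalidMoleculeError
from .krfp_synthetic import KRFP_N_KEYS, compiled_keys

ECFP4 = "ecfp4"
KRFP = "krfp"

_morgan_cache: dict[int, rdFingerprintGenerator.FingerprintGenerator64] = {}


@dataclass
class FingerprintVector:
    """A fixed-length bit vector with its type tag."""

    bits: np.ndarray  # uint8 array of 0/1
    fp_type: str

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("bits must be one-dimensional")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be binary")
        if self.fp_type == KRFP and len(self.bits) != KRFP_N_KEYS:
            raise ValueError(f"KRFP vectors must have length {KRFP_N_KEYS}")

    @property
    def length(self) -> int:
        return int(len(self.bits))

    def popcount(self) -> int:
        return int(self.bits.sum())


def _as_mol(rec: Union[MoleculeRecord, str, Chem.Mol]) -> Chem.Mol:
    if isinstance(rec, MoleculeRecord):
        mol = rec.mol()
    elif isinstance(rec, str):
        mol = Chem.MolFromSmiles(rec)
    else:
        mol = rec
    if mol is None:
        raise InvalidMoleculeError(str(rec))
    return mol


def compute_fingerprint(
    rec: Union[MoleculeRecord, str, Chem.Mol],
    fp_type: str = ECFP4,
    n_bits: int = 2048,
) -> FingerprintVector:
    """Compute a deterministic binary fingerprint.

    ``ecfp4`` is the radius-2 circular (Morgan) fingerprint folded to
    ``n_bits``; ``krfp`` sets bit ``i`` iff substructure key ``i`` of the
    4860-key inventory occurs in the molecule.
    """
    mol = _as_mol(rec)
    if fp_type == ECFP4:
        if n_bits not in _morgan_cache:
            _morgan_cache[n_bits] = rdFingerprintGenerator.GetMorganGenerator(
                radius=2, fpSize=n_bits
            )
        fp = _morgan_cache[n_bits].GetFingerprintAsNumPy(mol)
        return FingerprintVector(fp.astype(np.uint8), ECFP4)
    if fp_type == KRFP:
        bits = np.zeros(KRFP_N_KEYS, dtype=np.uint8)
        for i, query in enumerate(compiled_keys()):
            if mol.HasSubstructMatch(query):
                bits[i] = 1
        return FingerprintVector(bits, KRFP)
    raise ValueError(f"unknown fingerprint type {fp_type!r}")


def tanimoto_distance(a: FingerprintVector, b: FingerprintVector) -> float:
    """1 - |a AND b| / |a OR b|; two all-zero vectors have distance 0."""
    if a.fp_type != b.fp_type or a.length != b.length:
        raise IncompatibleFingerprintsError(
            f"cannot compare {a.fp_type}/{a.length} with {b.fp_type}/{b.length}"
        )
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    return 1.0 - inter / union


def flip_bits(fp: FingerprintVector, k: int, seed: int) -> FingerprintVector:
    """Flip exactly ``k`` distinct bit positions chosen uniformly at random."""
    if not (0 <= k <= fp.length):
        raise ValueError(f"k must be in [0, {fp.length}], got {k}")
    rng = np.random.default_rng(seed)
    out = fp.bits.copy()
    if k:
        idx = rng.choice(fp.length, size=k, replace=False)
        out[idx] ^= 1
    return FingerprintVector(out, fp.fp_type)
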