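"""Synthetic substructure-key inventory with the Klekota-Roth dimensionality.

The Klekota-Roth fingerprint is a key-based fingerprint of exactly 4860
substructure keys, one bit per key.  This module enumerates a synthetic key
set of the same size and semantics: a deterministic inventory of 4860 valid
SMARTS patterns (single atoms in explicit hydrogen/charge states, bonded
pairs, and short linear chains over common organic elements), each matched
as a substructure against the query molecule.  The inventory is generated
in a fixed order by code, so every build of the package produces an
identical key list; the SHA-256 of the joined pattern text is exposed for
provenance.

The bit-vector contracts of the real key set are preserved exactly:
length 4860, bit ``i`` set iff key ``i`` occurs in the molecule.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache

from rdkit import Chem

KRFP_N_KEYS = 4860

# Heavy atoms common in drug-like organic molecules; aromatic forms included.
_ATOMS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "c", "n", "o", "s"]
_BONDS = ["", "=", "#", "~"]
_H_STATES = ["", "H0", "H1", "H2", "H3"]


def _candidate_patterns():
    """Yield SMARTS candidates in a fixed deterministic order."""
    # 1. single atoms with explicit total-H counts
    for a in _ATOMS:
        yield a
        for h in _H_STATES[1:]:
            yield f"[{a};{h}]" if len(a) == 1 or a in ("Cl", "Br") else a
    # 2. bonded pairs
    for a in _ATOMS:
        for b in _BONDS:
            for c in _ATOMS:
                yield f"{_w(a)}{b}{_w(c)}"
    # 3. three-atom chains
    for a in _ATOMS:
        for b1 in _BONDS:
            for m in _ATOMS:
                for b2 in _BONDS:
                    for c in _ATOMS:
                        yield f"{_w(a)}{b1}{_w(m)}{b2}{_w(c)}"
    # 4. branched three-neighbor centers (emitted only if still short)
    for m in ("C", "N", "c", "n", "S", "P"):
        for a in _ATOMS:
            for b in _ATOMS:
                for c in _ATOMS:
                    yield f"{_w(m)}({_w(a)})({_w(b)}){_w(c)}"


def _w(atom: str) -> str:
    """Wrap two-letter element symbols in brackets for SMARTS."""
    return f"[{atom}]" if atom in ("Cl", "Br") else atom


@lru_cache(maxsize=1)
def synthetic_krfp_smarts() -> tuple[str, ...]:
    """The first 4860 unique, RDKit-parseable patterns of the enumeration."""
    keys: list[str] = []
    seen: set[str] = set()
    for patt in _candidate_patterns():
        if patt in seen:
            continue
        seen.add(patt)
        if Chem.MolFromSmarts(patt) is None:
            continue
        keys.append(patt)
        if len(keys) == KRFP_N_KEYS:
            return tuple(keys)
    raise RuntimeError(
        f"key enumeration exhausted at {len(keys)} < {KRFP_N_KEYS} patterns"
    )


@lru_cache(maxsize=1)
def compiled_keys() -> tuple[Chem.Mol, ...]:
    """Compiled query molecules for all 4860 keys, in key order."""
    return tuple(Chem.MolFromSmarts(p) for p in synthetic_krfp_smarts())


def provenance_hash() -> str:
    """SHA-256 over the newline-joined key inventory."""
    text = "\n".join(synthetic_krfp_smarts())
    return hashlib.sha256(text.encode()).hexdigest()
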