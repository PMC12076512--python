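"""A valence-constrained, total molecular token notation (SELFIES dialect).

Every sequence of tokens from the alphabet derives a chemically valid
molecule: bond orders requested by a token are capped by the remaining
valence of both partner atoms, branch and ring tokens that cannot be
realized are skipped, and derivation stops early when the growing chain
runs out of free valence.  Conversion works on kekulized structures, so
aromaticity is expressed through alternating single/double bonds and
recovered by sanitization after decoding.

Grammar
-------
* atom tokens ``[C] [=C] [#C] ...`` append one atom, bonded to the current
  chain head with the requested order (capped by free valences);
* ``[BranchK]`` reads K index tokens giving ``N`` and derives the next
  ``N + 1`` tokens as a branch hanging off the current chain head;
* ``[RingK]`` / ``[=RingK]`` reads K index tokens giving ``N`` and bonds
  the chain head to the atom derived ``N + 1`` steps earlier;
* indices are read base 16; the first 16 alphabet tokens double as digits.
"""

from __future__ import annotations

import re

from rdkit import Chem

from ..errors import OutOfVocabularyError, UnconvertibleError

# (element symbol, bond order to the previous atom, forced explicit H count)
_ATOM_TOKENS: dict[str, tuple[str, int, int | None]] = {
    "[C]": ("C", 1, None),
    "[=C]": ("C", 2, None),
    "[#C]": ("C", 3, None),
    "[N]": ("N", 1, None),
    "[=N]": ("N", 2, None),
    "[#N]": ("N", 3, None),
    "[NH]": ("N", 1, 1),
    "[O]": ("O", 1, None),
    "[=O]": ("O", 2, None),
    "[S]": ("S", 1, None),
    "[=S]": ("S", 2, None),
    "[P]": ("P", 1, None),
    "[=P]": ("P", 2, None),
    "[F]": ("F", 1, None),
    "[Cl]": ("Cl", 1, None),
    "[Br]": ("Br", 1, None),
    "[I]": ("I", 1, None),
    "[B]": ("B", 1, None),
    # terminal explicit-hydrogen groups (decoder-only convenience tokens)
    "[CH3]": ("C", 1, 3),
    "[NH2]": ("N", 1, 2),
    "[OH]": ("O", 1, 1),
    "[SH]": ("S", 1, 1),
}

_BRANCH_TOKENS = {"[Branch1]": 1, "[Branch2]": 2}
_RING_TOKENS = {"[Ring1]": (1, 1), "[Ring2]": (2, 1), "[=Ring1]": (1, 2), "[=Ring2]": (2, 2)}

ALPHABET: tuple[str, ...] = tuple(_ATOM_TOKENS) + tuple(_BRANCH_TOKENS) + tuple(_RING_TOKENS)

# the first 16 alphabet tokens double as base-16 digits in index positions
_INDEX_TOKENS = ALPHABET[:16]
_INDEX_OF = {t: i for i, t in enumerate(_INDEX_TOKENS)}

# maximum total valence per element (explicit bonds never exceed this, so
# RDKit's implicit-hydrogen fill always reaches an allowed valence state)
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 6, "P": 5, "F": 1,
                "Cl": 1, "Br": 1, "I": 1, "B": 3}

_TOKEN_RE = re.compile(r"\[[^\]]*\]")


def split_tokens(s: str) -> list[str]:
    """Split a bracketed token string into tokens, validating coverage."""
    tokens = _TOKEN_RE.findall(s)
    if "".join(tokens) != s.replace(" ", ""):
        raise UnconvertibleError(f"not a token string: {s!r}")
    return tokens


def _free(atom: Chem.Atom, caps: dict[int, int]) -> int:
    return caps[atom.GetIdx()]


def decode(selfies: str | list[str]) -> str:
    """Derive a molecule from a token sequence; total on the alphabet.

    Returns the canonical SMILES of the derived molecule.  The only way to
    fail is a sequence deriving zero atoms, which raises
    :class:`~profis.errors.UnconvertibleError`.
    """
    tokens = split_tokens(selfies) if isinstance(selfies, str) else list(selfies)
    for t in tokens:
        if t not in _ATOM_TOKENS and t not in _BRANCH_TOKENS and t not in _RING_TOKENS:
            raise OutOfVocabularyError(t, tokens.index(t))
    mol = Chem.RWMol()
    caps: dict[int, int] = {}
    order: list[int] = []  # atom indices in derivation order
    _derive(tokens, 0, len(tokens), mol, None, caps, order)
    if mol.GetNumAtoms() == 0:
        raise UnconvertibleError("token sequence derives no atoms")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - guarded by valence caps
        raise UnconvertibleError(f"sanitization failed: {exc}") from exc
    return Chem.MolToSmiles(mol)


_BOND_OF = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def _derive(tokens, start, end, mol, parent, caps, order) -> None:
    """Derive tokens[start:end] growing from atom ``parent`` (an index or
    None for the root of the whole string)."""
    i = start
    while i < end:
        tok = tokens[i]
        i += 1
        if tok in _ATOM_TOKENS:
            sym, want, hs = _ATOM_TOKENS[tok]
            if parent is not None and caps[parent] == 0:
                return  # chain head saturated: derivation of this region ends
            atom = Chem.Atom(sym)
            cap = _MAX_VALENCE[sym] - (hs or 0)
            if hs is not None:
                atom.SetNumExplicitHs(hs)
            idx = mol.AddAtom(atom)
            if parent is None:
                caps[idx] = cap
            else:
                bond = min(want, caps[parent], cap)
                bond = max(bond, 1)
                mol.AddBond(parent, idx, _BOND_OF[bond])
                caps[parent] -= bond
                caps[idx] = cap - bond
            order.append(idx)
            parent = idx
        elif tok in _BRANCH_TOKENS:
            if parent is None or caps[parent] < 1:
                continue  # non-applicable branch token acts as a no-op
            k = _BRANCH_TOKENS[tok]
            n, i = _read_index(tokens, i, end, k)
            stop = min(i + n + 1, end)
            if stop > i:
                _derive(tokens, i, stop, mol, parent, caps, order)
            i = stop
        else:
            if parent is None:
                continue  # non-applicable ring token acts as a no-op
            k, want = _RING_TOKENS[tok]
            n, i = _read_index(tokens, i, end, k)
            pos = order.index(parent)
            tpos = max(pos - (n + 1), 0)
            target = order[tpos]
            if target == parent:
                continue
            if mol.GetBondBetweenAtoms(parent, target) is not None:
                continue
            bond = min(want, caps[parent], caps[target])
            if bond < 1:
                continue
            mol.AddBond(parent, target, _BOND_OF[bond])
            caps[parent] -= bond
            caps[target] -= bond


def _read_index(tokens, i, end, k) -> tuple[int, int]:
    """Read k base-16 digit tokens; missing or non-digit tokens count 0."""
    n = 0
    for _ in range(k):
        digit = 0
        if i < end:
            digit = _INDEX_OF.get(tokens[i], 0)
            i += 1
        n = n * 16 + digit
    return n, i


def _index_tokens(n: int, k: int) -> list[str]:
    digits = []
    for _ in range(k):
        digits.append(_INDEX_TOKENS[n % 16])
        n //= 16
    return digits[::-1]


# ---------------------------------------------------------------------------
# encoding: kekulized SMILES -> token string

_SMILES_RE = re.compile(r"(\[[^\]]+\]|Cl|Br|%\d{2}|[BCNOPSFI]|[=#\-/\\()]|\d)")

_BOND_ORDER = {"": 1, "-": 1, "=": 2, "#": 3, "/": 1, "\\": 1}


def encode(smiles: str) -> str:
    """Convert a SMILES string to the token notation.

    The structure is kekulized first; conversion fails (with
    :class:`~profis.errors.UnconvertibleError`) for elements or charge
    states outside the alphabet.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnconvertibleError(f"unparseable SMILES {smiles!r}")
    kek = Chem.MolToSmiles(mol, kekuleSmiles=True)
    items, _ = _parse(kek)
    tokens: list[str] = []
    counter = [0]
    _emit(items, tokens, counter)
    return "".join(tokens)


def _parse(smiles: str):
    """Parse kekulized SMILES into a nested item tree with atom ids."""
    pos = 0
    counter = [0]
    ring_open: dict[str, tuple[int, int]] = {}

    def parse_seq(pos):
        items = []
        pending = ""
        while pos < len(smiles):
            ch = smiles[pos]
            if ch == ")":
                return items, pos
            if ch == "(":
                sub, pos = parse_seq(pos + 1)
                if pos >= len(smiles) or smiles[pos] != ")":
                    raise UnconvertibleError(f"unbalanced branch in {smiles!r}")
                pos += 1
                items.append(("branch", sub))
                continue
            m = _SMILES_RE.match(smiles, pos)
            if not m:
                raise UnconvertibleError(f"cannot lex {smiles!r} at {pos}")
            tok = m.group(0)
            pos = m.end()
            if tok in "-=#/\\":
                pending = tok
            elif tok.isdigit() or tok.startswith("%"):
                if tok in ring_open:
                    open_atom, open_bond = ring_open.pop(tok)
                    bond = _BOND_ORDER[pending] if pending else open_bond
                    items.append(("ring", bond, open_atom))
                    pending = ""
                else:
                    ring_open[tok] = (counter[0] - 1, _BOND_ORDER.get(pending, 1))
                    pending = ""
            else:
                items.append(("atom", _BOND_ORDER.get(pending, 1), tok, counter[0]))
                counter[0] += 1
                pending = ""
        return items, pos

    items, pos = parse_seq(0)
    if pos != len(smiles) or ring_open:
        raise UnconvertibleError(f"dangling syntax in {smiles!r}")
    return items, counter[0]


_ELEMENT_TOKEN = {
    (sym, order): tok
    for tok, (sym, order, hs) in _ATOM_TOKENS.items()
    if hs is None
}


def _atom_token(raw: str, bond: int) -> str:
    if raw.startswith("["):
        m = re.fullmatch(r"\[([A-Za-z][a-z]?)(H\d?)?\]", raw)
        if not m:
            raise UnconvertibleError(f"atom {raw!r} outside the alphabet")
        sym, hs = m.groups()
        sym = sym.capitalize()
        if sym == "N" and hs in ("H", "H1") and bond == 1:
            return "[NH]"
        raise UnconvertibleError(f"atom {raw!r} outside the alphabet")
    tok = _ELEMENT_TOKEN.get((raw, bond))
    if tok is None:
        raise UnconvertibleError(f"no token for atom {raw!r} with bond {bond}")
    return tok


def _emit(items, tokens, counter) -> None:
    for item in items:
        if item[0] == "atom":
            _, bond, raw, _aid = item
            tokens.append(_atom_token(raw, bond))
            counter[0] += 1
        elif item[0] == "branch":
            sub: list[str] = []
            _emit(item[1], sub, counter)
            n = len(sub) - 1
            k = 1 if n < 16 else 2
            tokens.append(f"[Branch{k}]")
            tokens.extend(_index_tokens(n, k))
            tokens.extend(sub)
        else:
            _, bond, open_atom = item
            n = counter[0] - 1 - open_atom - 1
            if n < 0:
                raise UnconvertibleError("ring closure to the same atom")
            k = 1 if n < 16 else 2
            prefix = "=" if bond == 2 else ""
            if bond > 2:
                raise UnconvertibleError("triple ring closures unsupported")
            tokens.append(f"[{prefix}Ring{k}]")
            tokens.extend(_index_tokens(n, k))
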