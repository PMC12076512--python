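"""SMILES <-> DeepSMILES conversion.

DeepSMILES replaces the two syntactic features of SMILES that generative
sequence models most often get wrong:

* ring bonds: the matched pair of ring-closure digits becomes a single
  number written at the ring-closing atom, whose value is the ring size
  (atom count along the current path, the closing bond included);
* branches: the opening parenthesis disappears and each branch is closed
  by as many ``)`` symbols as the branch holds atoms.

Decoding keeps a stack of atoms on the current path: every new atom bonds
to the top of the stack and is pushed, ``)`` pops one atom, and a ring
number ``n`` bonds the top atom to the atom ``n - 1`` positions below it.
"""

from __future__ import annotations

import re

from rdkit import Chem

from ..errors import UnconvertibleError

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Cl|Br|%\d{2}|[BCNOPSFIbcnops]|[=#\-~/\\()]|\d)"
)
_ORGANIC = {"B", "C", "N", "O", "P", "S", "F", "I", "Cl", "Br"}
_AROMATIC = {"b", "c", "n", "o", "p", "s"}

_BOND_TYPES = {
    "-": Chem.BondType.SINGLE,
    "=": Chem.BondType.DOUBLE,
    "#": Chem.BondType.TRIPLE,
}


def _lex(s: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if not m:
            raise UnconvertibleError(f"cannot lex {s!r} at position {pos}")
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def encode(smiles: str) -> str:
    """Convert a (canonical, stereo-free) SMILES string to DeepSMILES."""
    tokens = _lex(smiles)
    out: list[str] = []
    path: list[int] = []  # atom ids on the current path (root..current)
    branch_marks: list[int] = []  # path length at each open branch
    ring_open: dict[str, tuple[int, str]] = {}  # digit -> (atom id, bond)
    atom_pos: dict[int, int] = {}  # atom id -> index in path when pushed
    next_id = 0
    pending_bond = ""
    for tok in tokens:
        if tok == "(":
            branch_marks.append(len(path))
        elif tok == ")":
            if not branch_marks:
                raise UnconvertibleError(f"unbalanced ')' in {smiles!r}")
            mark = branch_marks.pop()
            out.append(")" * (len(path) - mark))
            del path[mark:]
        elif tok in "-=#~/\\":
            if tok in "/\\":  # stereo bonds are stripped upstream
                continue
            pending_bond = tok
        elif tok.isdigit() or tok.startswith("%"):
            digit = tok
            if digit in ring_open:
                open_atom, open_bond = ring_open.pop(digit)
                if open_atom not in path:
                    raise UnconvertibleError(
                        f"ring partner not on current path in {smiles!r}"
                    )
                size = len(path) - path.index(open_atom)
                bond = pending_bond or open_bond
                sym = str(size) if size < 10 else f"%{size}"
                out.append(bond + sym)
            else:
                ring_open[digit] = (path[-1], pending_bond)
            pending_bond = ""
        else:  # atom token
            out.append(pending_bond + tok)
            pending_bond = ""
            path.append(next_id)
            atom_pos[next_id] = len(path) - 1
            next_id += 1
    if ring_open:
        raise UnconvertibleError(f"unclosed ring bond in {smiles!r}")
    return "".join(out)


def _make_atom(tok: str) -> Chem.Atom:
    if tok.startswith("["):
        inner = tok[1:-1]
        m = re.fullmatch(r"([A-Za-z][a-z]?)(H\d?)?([+-]\d?)?", inner)
        if not m:
            raise UnconvertibleError(f"unsupported bracket atom {tok!r}")
        sym, hs, charge = m.groups()
        aromatic = sym.islower()
        atom = Chem.Atom(sym.capitalize())
        atom.SetIsAromatic(aromatic)
        if hs:
            atom.SetNumExplicitHs(int(hs[1:]) if len(hs) > 1 else 1)
            atom.SetNoImplicit(True)
        if charge:
            sign = 1 if charge[0] == "+" else -1
            atom.SetFormalCharge(sign * (int(charge[1:]) if len(charge) > 1 else 1))
        return atom
    aromatic = tok in _AROMATIC
    atom = Chem.Atom(tok.capitalize())
    atom.SetIsAromatic(aromatic)
    return atom


def decode(deep: str) -> str:
    """Convert a DeepSMILES string back to canonical SMILES.

    Raises :class:`~profis.errors.UnconvertibleError` when the string does
    not describe a chemically valid molecule.
    """
    try:
        tokens = _lex(deep)
    except UnconvertibleError:
        raise
    if "(" in tokens:
        raise UnconvertibleError("DeepSMILES has no opening parenthesis")
    mol = Chem.RWMol()
    path: list[int] = []
    pending_bond = ""
    ring_sizes: list[tuple[int, int, str]] = []
    for tok in tokens:
        if tok == ")":
            if not path:
                raise UnconvertibleError("')' with empty path")
            path.pop()
        elif tok in "-=#~/\\":
            pending_bond = tok
        elif tok.isdigit() or tok.startswith("%"):
            size = int(tok[1:]) if tok.startswith("%") else int(tok)
            if size < 2 or size > len(path):
                raise UnconvertibleError(f"ring size {size} exceeds path")
            a, b = path[-1], path[-size]
            if a == b or mol.GetBondBetweenAtoms(a, b) is not None:
                raise UnconvertibleError("degenerate ring closure")
            ring_sizes.append((a, b, pending_bond))
            pending_bond = ""
        elif tok == "(":  # pragma: no cover - filtered above
            raise UnconvertibleError("'(' not allowed")
        else:
            atom = _make_atom(tok)
            idx = mol.AddAtom(atom)
            if path:
                prev = path[-1]
                mol.AddBond(prev, idx, _pick_bond(mol, prev, idx, pending_bond))
            pending_bond = ""
            path.append(idx)
    for a, b, bond in ring_sizes:
        mol.AddBond(a, b, _pick_bond(mol, a, b, bond))
    if mol.GetNumAtoms() == 0:
        raise UnconvertibleError("empty molecule")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise UnconvertibleError(f"sanitization failed: {exc}") from exc
    return Chem.MolToSmiles(mol)


def _pick_bond(mol: Chem.RWMol, a: int, b: int, bond: str) -> Chem.BondType:
    if bond in _BOND_TYPES:
        return _BOND_TYPES[bond]
    if bond == "~":
        return Chem.BondType.SINGLE
    if (
        mol.GetAtomWithIdx(a).GetIsAromatic()
        and mol.GetAtomWithIdx(b).GetIsAromatic()
    ):
        return Chem.BondType.AROMATIC
    return Chem.BondType.SINGLE
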