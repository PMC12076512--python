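"""Molecule standardization, training-set filters, scaffolds and the
scaffold-grouped train/test split.

Standardization keeps the largest organic fragment, neutralizes charges,
strips all stereochemistry and emits one canonical SMILES per structure,
so that repeated standardization is a fixed point.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import InvalidMoleculeError

RDLogger.DisableLog("rdApp.*")

_UNCHARGER = rdMolStandardize.Uncharger()


@dataclass
class MoleculeRecord:
    """A standardized molecule with its scaffold and optional activity."""

    raw_input: str
    canonical_smiles: str
    scaffold_smiles: str = ""
    mol_weight: float = 0.0
    activity_ki: Optional[float] = None  # nM
    activity_class: Optional[str] = None  # "active" / "inactive"
    extra: dict = field(default_factory=dict)

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.canonical_smiles)


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the fragment with the most heavy atoms; break ties by the
    lexicographically smallest canonical SMILES."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    keyed = []
    for f in frags:
        try:
            smi = Chem.MolToSmiles(f)
        except Exception:
            continue
        keyed.append((f.GetNumHeavyAtoms(), smi, f))
    if not keyed:
        raise ValueError("no scorable fragment")
    keyed.sort(key=lambda t: (-t[0], t[1]))
    return keyed[0][2]


def standardize(raw: str) -> MoleculeRecord:
    """Standardize a raw SMILES string into a :class:`MoleculeRecord`.

    Counterions are removed (largest organic fragment kept), charges are
    neutralized where chemically possible, stereo descriptors are discarded
    and the canonical SMILES is computed.  Raises
    :class:`~profis.errors.InvalidMoleculeError` for unparseable input.
    """
    if not raw or not raw.strip():
        raise InvalidMoleculeError(raw, "empty input")
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise InvalidMoleculeError(raw)
    try:
        mol = _largest_organic_fragment(mol)
        mol = _UNCHARGER.uncharge(mol)
        Chem.RemoveStereochemistry(mol)
        canonical = Chem.MolToSmiles(mol)
        mol = Chem.MolFromSmiles(canonical)
        if mol is None:
            raise ValueError("canonicalization produced unparseable SMILES")
    except InvalidMoleculeError:
        raise
    except Exception as exc:  # pragma: no cover - rdkit internal failures
        raise InvalidMoleculeError(raw, str(exc)) from exc
    return MoleculeRecord(
        raw_input=raw,
        canonical_smiles=canonical,
        scaffold_smiles=murcko_scaffold_smiles(mol),
        mol_weight=Descriptors.MolWt(mol),
    )


def passes_training_filters(rec: MoleculeRecord) -> bool:
    """Training-set inclusion: molecular weight within 200-450 g/mol and no
    violation of the four classic rule-of-five criteria (MW <= 500,
    clogP <= 5, HBD <= 5, HBA <= 10)."""
    mol = rec.mol()
    if mol is None:
        return False
    mw = Descriptors.MolWt(mol)
    if not (200.0 <= mw <= 450.0):
        return False
    if mw > 500.0:
        return False
    if Crippen.MolLogP(mol) > 5.0:
        return False
    if Lipinski.NumHDonors(mol) > 5:
        return False
    if Lipinski.NumHAcceptors(mol) > 10:
        return False
    return True


def murcko_scaffold_smiles(mol_or_smiles) -> str:
    """Bemis-Murcko framework (ring systems plus linkers, side chains
    removed) as canonical SMILES; empty string for acyclic molecules."""
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
    else:
        mol = mol_or_smiles
    if mol is None:
        raise InvalidMoleculeError(str(mol_or_smiles))
    if mol.GetRingInfo().NumRings() == 0:
        return ""
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def murcko_scaffold(rec: MoleculeRecord) -> str:
    return murcko_scaffold_smiles(rec.canonical_smiles)


def scaffold_split(
    records: Sequence[MoleculeRecord],
    train_frac: float = 0.9,
    seed: int = 0,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Scaffold-grouped train/test split.

    Molecules are grouped by Bemis-Murcko scaffold (all acyclic molecules
    form one shared group).  Groups are drawn in seeded random order and a
    group joins the training set only while the resulting training set stays
    within ``train_frac`` of the dataset; otherwise the whole group goes to
    the test set.  A scaffold therefore never straddles the two partitions.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    groups: dict[str, list[MoleculeRecord]] = {}
    for rec in records:
        groups.setdefault(rec.scaffold_smiles, []).append(rec)
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    cap = train_frac * len(records)
    train: list[MoleculeRecord] = []
    test: list[MoleculeRecord] = []
    for key in keys:
        grp = groups[key]
        if len(train) + len(grp) <= cap:
            train.extend(grp)
        else:
            test.extend(grp)
    return train, test


def read_molecules(path: str | Path) -> list[MoleculeRecord]:
    """Read molecules from a one-SMILES-per-line file or a CSV with a
    ``smiles`` column and an optional ``ki_nm`` column."""
    path = Path(path)
    records: list[MoleculeRecord] = []
    with open(path, newline="") as fh:
        first = fh.readline()
        fh.seek(0)
        if "," in first and "smiles" in first.lower():
            reader = csv.DictReader(fh)
            fields = {k.lower(): k for k in reader.fieldnames or []}
            smiles_col = fields["smiles"]
            ki_col = fields.get("ki_nm")
            for row in reader:
                rec = standardize(row[smiles_col])
                if ki_col and row.get(ki_col, "") not in ("", None):
                    rec.activity_ki = float(row[ki_col])
                records.append(rec)
        else:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    records.append(standardize(line))
    return records


def write_molecules(
    records: Iterable[MoleculeRecord], path: str | Path, split: Optional[dict] = None
) -> None:
    """Write records as CSV mirroring the input with added
    ``canonical_smiles,scaffold,split`` columns."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", "canonical_smiles", "scaffold", "ki_nm", "split"])
        for rec in records:
            writer.writerow(
                [
                    rec.raw_input,
                    rec.canonical_smiles,
                    rec.scaffold_smiles,
                    "" if rec.activity_ki is None else rec.activity_ki,
                    (split or {}).get(rec.canonical_smiles, ""),
                ]
            )
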