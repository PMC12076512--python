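"""Deterministic synthetic data: drug-like molecule corpora assembled from
a fragment inventory, and activity datasets with a known generative rule.

The corpus generator composes two ring-bearing fragments with a short
linker (``core + linker + core``) at the SMILES-string level, so every
generated string is valid by construction, already standardized (neutral,
stereo-free, single fragment) and controllable in molecular weight.  The
activity rule plants a pharmacophore substructure (a sulfonamide by
default): molecules containing it receive a pKi boost large enough to make
the active class detectable from the fingerprint, mirroring how a real
ligand set carries substructure-driven affinity signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import Chem

from .chem import MoleculeRecord, standardize
from .errors import InfeasibleSpecError

# fragments attach through their first written atom
DEFAULT_CORES = (
    "c1ccccc1",
    "c1ccc(F)cc1",
    "c1ccc(Cl)cc1",
    "c1ccc(C)cc1",
    "c1ccc(OC)cc1",
    "c1ccc(C(F)(F)F)cc1",
    "c1ccncc1",
    "c1cccnc1",
    "c1ccc2ccccc2c1",
    "c1cccs1",
    "c1ccco1",
    "c1cc[nH]c1",
    "C1CCCCC1",
    "C1CCNCC1",
    "N1CCCCC1",
    "N1CCN(C)CC1",
    "C1CCOCC1",
)

# linkers connect their first and last written atoms to the two cores
DEFAULT_LINKERS = (
    "CC",
    "CCC",
    "CCCC",
    "CCCCC",
    "COC",
    "CCOC",
    "CNC",
    "CCNC",
    "C(=O)N",
    "CC(=O)N",
    "C(=O)NC",
    "CC(=O)NC",
    "C(=O)OC",
    "CN(C)C",
    "S(=O)(=O)N",
    "CS(=O)(=O)N",
    "S(=O)(=O)NC",
)

PHARMACOPHORE = "S(=O)(=O)N"  # sulfonamide


@dataclass
class FixtureSpec:
    """Parameters of the synthetic corpus and its activity rule."""

    n_molecules: int = 500
    seed: int = 0
    cores: tuple[str, ...] = DEFAULT_CORES
    linkers: tuple[str, ...] = DEFAULT_LINKERS
    mw_range: tuple[float, float] = (200.0, 450.0)
    min_scaffolds: int = 10
    # activity rule: pKi = base + effect * [has pharmacophore] + N(0, noise)
    pharmacophore: str = PHARMACOPHORE
    base_pki: float = 6.0
    effect_pki: float = 3.0
    noise_sd: float = 0.3


def make_corpus(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Generate ``n_molecules`` unique, standardized drug-like molecules."""
    rng = np.random.default_rng(spec.seed)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    lo, hi = spec.mw_range
    attempts = 0
    max_attempts = 200 * spec.n_molecules
    while len(records) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise InfeasibleSpecError(
                f"only {len(records)} of {spec.n_molecules} molecules reachable "
                f"within MW range {spec.mw_range}"
            )
        core_a = spec.cores[rng.integers(len(spec.cores))]
        core_b = spec.cores[rng.integers(len(spec.cores))]
        linker = spec.linkers[rng.integers(len(spec.linkers))]
        smiles = core_a + linker + core_b
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pragma: no cover - inventory is valid by design
            continue
        rec = standardize(smiles)
        if rec.canonical_smiles in seen:
            continue
        if not (lo <= rec.mol_weight <= hi):
            continue
        seen.add(rec.canonical_smiles)
        records.append(rec)
    n_scaffolds = len({r.scaffold_smiles for r in records})
    if n_scaffolds < min(spec.min_scaffolds, max(1, spec.n_molecules // 3)):
        raise InfeasibleSpecError(
            f"corpus has only {n_scaffolds} distinct scaffolds"
        )
    return records


def make_activity_dataset(
    spec: FixtureSpec, records: Optional[list[MoleculeRecord]] = None
) -> list[tuple[MoleculeRecord, float]]:
    """Attach K_i values (nM) drawn from the fixture's activity rule.

    pKi = base + effect * 1[pharmacophore present] + Gaussian noise;
    K_i[nM] = 10 ** (9 - pKi).
    """
    if records is None:
        records = make_corpus(spec)
    rng = np.random.default_rng(spec.seed + 1)
    query = Chem.MolFromSmarts(spec.pharmacophore)
    out = []
    for rec in records:
        has = rec.mol().HasSubstructMatch(query)
        pki = spec.base_pki + spec.effect_pki * float(has) + rng.normal(0, spec.noise_sd)
        ki_nm = 10.0 ** (9.0 - pki)
        rec.activity_ki = ki_nm
        out.append((rec, ki_nm))
    return out


def make_latent_activity_dataset(
    n: int = 500,
    dim: int = 32,
    separation: float = 6.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Separable synthetic latent vectors: two displaced Gaussians.

    Returns ``(Z, y)`` with labels 1 for the displaced cluster.  With the
    default separation of six noise standard deviations along a random
    direction the classes are essentially perfectly separable.
    """
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=dim)
    direction /= np.linalg.norm(direction)
    y = (rng.random(n) < 0.5).astype(int)
    Z = rng.normal(0, noise_sd, size=(n, dim)) + np.outer(y, separation * direction)
    return Z, y


def make_dm_dataset(
    n_train: int = 300,
    n_test_per_level: int = 120,
    displacements: tuple[float, ...] = (0.0, 0.4, 1.0, 2.5),
    dim: int = 8,
    n_centers: int = 12,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Training latents plus test sets progressively displaced from the
    training support, for applicability-domain profiling.

    The generative rule is patchy: ``n_centers`` cluster centers carry
    alternating activity labels and every point inherits the label of its
    nearest center.  Test points start on the training support and are
    pushed outward by growing random displacements, so prediction error
    grows with distance to the training data.

    Returns ``(Z_train, y_train, Z_test, y_test)``.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(n_centers, dim))
    labels = np.arange(n_centers) % 2

    def rule(Z: np.ndarray) -> np.ndarray:
        d = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        return labels[np.argmin(d, axis=1)]

    base = centers[rng.integers(n_centers, size=n_train)] + 0.25 * rng.normal(
        size=(n_train, dim)
    )
    y_train = rule(base)
    test_blocks, test_labels = [], []
    for delta in displacements:
        # start on the training support (jittered training points), then
        # push outward by the displacement
        pts = base[rng.integers(n_train, size=n_test_per_level)] + 0.03 * rng.normal(
            size=(n_test_per_level, dim)
        )
        direction = rng.normal(size=(n_test_per_level, dim))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        pts = pts + delta * direction
        test_blocks.append(pts)
        test_labels.append(rule(pts))
    return base, y_train, np.vstack(test_blocks), np.concatenate(test_labels)
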