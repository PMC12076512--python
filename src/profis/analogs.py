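"""Analog-library generation by fingerprint noising, latent neighborhood
and interpolation exploration, scaffold-novelty scoring, and property
profiling.

Analog generation perturbs the seed molecule's fingerprint by flipping a
few random bits, then passes each noised copy through the deterministic
encoder path and greedy decoder: output diversity is therefore
attributable to the fingerprint noise alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED

from .chem import MoleculeRecord, murcko_scaffold_smiles, standardize
from .codecs import to_smiles
from .fingerprints import (
    FingerprintVector,
    compute_fingerprint,
    flip_bits,
    tanimoto_distance,
)


@dataclass
class AnalogRecord:
    smiles: str
    distance_to_seed: float
    count: int = 1  # how many noised copies decoded to this structure


@dataclass
class AnalogReport:
    """Unique valid analogs of a seed molecule from noised fingerprints."""

    seed_smiles: str
    k_flips: int
    n_inputs: int
    outputs: list[AnalogRecord]
    validity_rate: float

    @property
    def n_unique(self) -> int:
        return len(self.outputs)

    def distances(self) -> np.ndarray:
        return np.array([o.distance_to_seed for o in self.outputs])


def generate_analogs(
    seed_smiles: str,
    model,
    n_copies: int,
    k_flips: int,
    seed: int = 0,
    n_bits: Optional[int] = None,
) -> AnalogReport:
    """Noise the seed fingerprint ``n_copies`` times (``k_flips`` random
    bits each), decode every copy through the mean-encoder/greedy-decoder
    path, and report unique valid outputs with their Tanimoto distance to
    the seed."""
    rec = standardize(seed_smiles)
    fp_type = model.cfg.fp_type
    n_bits = n_bits if n_bits is not None else model.cfg.fp_len
    seed_fp = compute_fingerprint(rec, fp_type, n_bits)
    noised = np.stack(
        [flip_bits(seed_fp, k_flips, seed + i).bits for i in range(n_copies)]
    )
    Z = np.atleast_2d(model.encode(noised, stochastic=False))
    decoded = model.decode_batch(Z)
    valid = 0
    by_smiles: dict[str, AnalogRecord] = {}
    for out in decoded:
        try:
            smi = to_smiles(out, model.vocab.notation)
        except Exception:
            continue
        valid += 1
        if smi in by_smiles:
            by_smiles[smi].count += 1
            continue
        out_fp = compute_fingerprint(smi, fp_type, n_bits)
        by_smiles[smi] = AnalogRecord(smi, tanimoto_distance(seed_fp, out_fp))
    return AnalogReport(
        seed_smiles=rec.canonical_smiles,
        k_flips=k_flips,
        n_inputs=n_copies,
        outputs=list(by_smiles.values()),
        validity_rate=valid / n_copies if n_copies else float("nan"),
    )


@dataclass
class NoveltyScore:
    smiles: str
    scaffold: str
    min_distance: float
    novel: bool
    acyclic: bool = False


def scaffold_novelty(
    generated: Sequence[MoleculeRecord | str],
    reference_scaffolds: Sequence[str],
    threshold: float = 0.25,
    fp_type: str = "ecfp4",
    n_bits: int = 2048,
) -> list[NoveltyScore]:
    """Score scaffold novelty of generated molecules against a reference
    scaffold set: the smallest Tanimoto distance between the generated
    molecule's Bemis-Murcko scaffold and any reference scaffold.  A
    molecule is novel when that distance reaches ``threshold``.

    Acyclic molecules have no scaffold; they are scored against the empty
    scaffold convention (distance 0 to an acyclic reference if present,
    else 1) and flagged ``acyclic``.
    """
    if not reference_scaffolds:
        raise ValueError("reference scaffold set must be non-empty")
    ref_has_empty = any(s == "" for s in reference_scaffolds)
    ref_fps = [
        compute_fingerprint(s, fp_type, n_bits)
        for s in reference_scaffolds
        if s != ""
    ]
    scores = []
    for item in generated:
        smi = item.canonical_smiles if isinstance(item, MoleculeRecord) else item
        scaffold = murcko_scaffold_smiles(smi)
        if scaffold == "":
            dist = 0.0 if ref_has_empty else 1.0
            scores.append(
                NoveltyScore(smi, "", dist, dist >= threshold, acyclic=True)
            )
            continue
        fp = compute_fingerprint(scaffold, fp_type, n_bits)
        dist = min(tanimoto_distance(fp, rf) for rf in ref_fps) if ref_fps else 1.0
        scores.append(NoveltyScore(smi, scaffold, dist, dist >= threshold))
    return scores


def latent_neighborhood(
    seed_smiles: str,
    model,
    radii: Sequence[float],
    n_per_radius: int,
    seed: int = 0,
) -> dict[float, dict]:
    """Decode points sampled uniformly on spheres of the given radii around
    the seed's mean embedding; report validity and the Tanimoto distance to
    the seed per radius."""
    rec = standardize(seed_smiles)
    fp_type, n_bits = model.cfg.fp_type, model.cfg.fp_len
    seed_fp = compute_fingerprint(rec, fp_type, n_bits)
    z0 = np.asarray(model.encode(seed_fp.bits, stochastic=False), dtype=float)
    rng = np.random.default_rng(seed)
    out: dict[float, dict] = {}
    for r in radii:
        if r == 0:
            Z = np.tile(z0, (n_per_radius, 1))
        else:
            dirs = rng.standard_normal((n_per_radius, len(z0)))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            Z = z0 + r * dirs
        decoded = model.decode_batch(Z)
        smiles, dists = [], []
        for s in decoded:
            try:
                smi = to_smiles(s, model.vocab.notation)
            except Exception:
                continue
            smiles.append(smi)
            dists.append(
                tanimoto_distance(seed_fp, compute_fingerprint(smi, fp_type, n_bits))
            )
        out[float(r)] = {
            "latents": Z,
            "smiles": smiles,
            "validity": len(smiles) / n_per_radius,
            "mean_distance": float(np.mean(dists)) if dists else float("nan"),
        }
    return out


def interpolate(
    smiles_a: str, smiles_b: str, steps: int, model
) -> list[tuple[np.ndarray, Optional[str]]]:
    """Decode ``steps`` points linearly interpolated between the mean
    embeddings of two molecules (endpoints included)."""
    if steps < 2:
        raise ValueError("steps must be >= 2")
    fp_type, n_bits = model.cfg.fp_type, model.cfg.fp_len
    za = np.asarray(
        model.encode(compute_fingerprint(standardize(smiles_a), fp_type, n_bits).bits)
    )
    zb = np.asarray(
        model.encode(compute_fingerprint(standardize(smiles_b), fp_type, n_bits).bits)
    )
    ts = np.linspace(0.0, 1.0, steps)
    Z = np.outer(1 - ts, za) + np.outer(ts, zb)
    decoded = model.decode_batch(Z)
    out = []
    for z, s in zip(Z, decoded):
        try:
            out.append((z, to_smiles(s, model.vocab.notation)))
        except Exception:
            out.append((z, None))
    return out


PROPERTY_COLUMNS = ("qed", "clogp", "tpsa", "hba", "hbd", "mw")


def property_profile(mols: Sequence[str | MoleculeRecord]) -> pd.DataFrame:
    """Per-molecule descriptor table (QED, clogP, TPSA, HBA, HBD, MW).

    Descriptor failures flag the row with ``ok = False`` instead of
    dropping it.  Distribution summaries are available via
    ``df.describe()``; the median/quartiles of each property are what the
    generated-library profiles report.
    """
    rows = []
    for item in mols:
        smi = item.canonical_smiles if isinstance(item, MoleculeRecord) else item
        row = {"smiles": smi, "ok": True}
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            row["ok"] = False
        else:
            try:
                row.update(
                    qed=QED.qed(mol),
                    clogp=Crippen.MolLogP(mol),
                    tpsa=Descriptors.TPSA(mol),
                    hba=Lipinski.NumHAcceptors(mol),
                    hbd=Lipinski.NumHDonors(mol),
                    mw=Descriptors.MolWt(mol),
                )
            except Exception:
                row["ok"] = False
        rows.append(row)
    return pd.DataFrame(rows)
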