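"""Bounded Bayesian optimization over the latent space, compound-library
assembly, and post-hoc drug-likeness filters.

The search box spans mu +/- k*sigma per latent dimension, estimated from a
reference embedding set (k = 2 by default; sweeping k trades output
validity against library diversity).  Optimization is Gaussian-process
guided: seeded quasi-random initial probes, then expected-improvement
acquisition over random candidates, optionally contracting the box around
the incumbent when an iteration fails to improve (sequential domain
reduction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, QED
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from .codecs import to_smiles


@dataclass
class SearchBox:
    """Per-dimension [low, high] bounds for the latent search."""

    low: np.ndarray
    high: np.ndarray
    bounds_multiplier: float = 2.0

    def __post_init__(self):
        self.low = np.asarray(self.low, dtype=float)
        self.high = np.asarray(self.high, dtype=float)
        if self.low.shape != self.high.shape or self.low.ndim != 1:
            raise ValueError("low/high must be equal-length vectors")
        if not (self.low < self.high).all():
            raise ValueError("low must be elementwise below high")

    @property
    def dim(self) -> int:
        return len(self.low)

    def contains(self, x: np.ndarray, atol: float = 1e-9) -> bool:
        return bool((x >= self.low - atol).all() and (x <= self.high + atol).all())

    def volume_log(self) -> float:
        return float(np.log(self.high - self.low).sum())


def compute_bounds(
    reference_Z: np.ndarray, k: float = 2.0, epsilon: float = 1e-3
) -> SearchBox:
    """Estimate the search box mu +/- k*sigma from reference embeddings.

    Dimensions with zero variance (or k = 0) are widened by ``epsilon``
    with a warning so the box stays non-degenerate.
    """
    Z = np.atleast_2d(np.asarray(reference_Z, dtype=float))
    if len(Z) < 2:
        raise ValueError("need at least two reference vectors")
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    low = mu - k * sd
    high = mu + k * sd
    degenerate = high - low <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate bound dimension(s) widened "
            f"by epsilon={epsilon}"
        )
        low[degenerate] -= epsilon
        high[degenerate] += epsilon
    return SearchBox(low, high, bounds_multiplier=k)


@dataclass
class ProbeRecord:
    x: np.ndarray
    value: float
    box_low: np.ndarray
    box_high: np.ndarray


def bayesian_maximize(
    objective: Callable[[np.ndarray], float],
    box: SearchBox,
    init_points: int = 4,
    n_iter: int = 20,
    domain_reduction: bool = False,
    contraction: float = 0.9,
    seed: int = 0,
    n_candidates: int = 512,
) -> tuple[np.ndarray, float, list[ProbeRecord]]:
    """Gaussian-process-guided maximization inside a (possibly shrinking)
    box.

    ``init_points`` seeded quasi-random (Sobol) probes are followed by
    ``n_iter`` expected-improvement probes.  With ``domain_reduction`` the
    box contracts by ``contraction`` around the incumbent after every
    iteration that fails to improve it.  Probes returning non-finite
    values are discarded from the surrogate with a warning.  Returns
    ``(best_x, best_value, probe_log)``.
    """
    rng = np.random.default_rng(seed)
    low, high = box.low.copy(), box.high.copy()
    sampler = qmc.Sobol(box.dim, scramble=True, seed=seed)
    X: list[np.ndarray] = []
    y: list[float] = []
    log: list[ProbeRecord] = []

    def probe(x: np.ndarray) -> None:
        val = float(objective(x))
        log.append(ProbeRecord(x.copy(), val, low.copy(), high.copy()))
        if not np.isfinite(val):
            warnings.warn("objective returned a non-finite value; probe discarded")
            return
        X.append(x)
        y.append(val)

    for row in sampler.random(init_points):
        probe(low + row * (high - low))

    kernel = Matern(nu=2.5, length_scale=np.ones(box.dim))
    for _ in range(n_iter):
        best = max(y) if y else -np.inf
        if len(y) >= 2:
            gp = GaussianProcessRegressor(
                kernel=kernel, alpha=1e-6, normalize_y=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(np.array(X), np.array(y))
            cand = low + rng.random((n_candidates, box.dim)) * (high - low)
            mu_c, sd_c = gp.predict(cand, return_std=True)
            sd_c = np.maximum(sd_c, 1e-12)
            imp = mu_c - best - 1e-4
            zsc = imp / sd_c
            ei = imp * norm.cdf(zsc) + sd_c * norm.pdf(zsc)
            x_next = cand[int(np.argmax(ei))]
        else:
            x_next = low + rng.random(box.dim) * (high - low)
        probe(x_next)
        if domain_reduction and y:
            improved = np.isfinite(log[-1].value) and log[-1].value >= best
            if not improved:
                center = X[int(np.argmax(y))]
                half = 0.5 * contraction * (high - low)
                new_low = np.maximum(center - half, low)
                new_high = np.minimum(center + half, high)
                ok = new_high > new_low
                low = np.where(ok, new_low, low)
                high = np.where(ok, new_high, high)
    if not y:
        raise RuntimeError("no finite probe values recorded")
    best_i = int(np.argmax(y))
    return X[best_i], y[best_i], log


@dataclass
class CandidateRecord:
    """One decoded latent candidate with its bookkeeping."""

    latent: np.ndarray
    decoded: str
    smiles: str  # canonical SMILES, empty when invalid
    valid: bool
    p_active: float
    source_seed: int
    is_incumbent: bool
    duplicate: bool = False  # same canonical SMILES already harvested
    passed_filters: bool = False
    properties: dict = field(default_factory=dict)


def generate_library(
    model,
    predict_proba: Callable[[np.ndarray], np.ndarray],
    box: SearchBox,
    n_runs: int = 10,
    init_points: int = 4,
    n_iter: int = 20,
    p_floor: float = 0.8,
    domain_reduction: bool = True,
    seed: int = 0,
) -> list[CandidateRecord]:
    """Run ``n_runs`` independent seeded searches maximizing the predicted
    activity and decode the harvested latents into a deduplicated library.

    Each search contributes its incumbent plus every probe whose predicted
    activity reaches ``p_floor``.  Validity of the decoded strings is
    recorded per candidate over all decodes; repeated canonical SMILES are
    kept but flagged ``duplicate`` so the deduplicated library is
    ``[r for r in records if r.valid and not r.duplicate]`` while validity
    accounting still covers every probe.
    """

    def objective_factory():
        def f(x: np.ndarray) -> float:
            p = predict_proba(x[None, :])
            p = p[:, 1] if np.ndim(p) == 2 else p
            return float(p[0])
        return f

    harvested: list[tuple[np.ndarray, float, int, bool]] = []
    for run in range(n_runs):
        run_seed = seed + 1000 * run
        best_x, _, log = bayesian_maximize(
            objective_factory(), box, init_points=init_points, n_iter=n_iter,
            domain_reduction=domain_reduction, seed=run_seed,
        )
        for rec in log:
            if np.isfinite(rec.value) and rec.value >= p_floor:
                harvested.append((rec.x, rec.value, run_seed, False))
        harvested.append(
            (best_x, float(objective_factory()(best_x)), run_seed, True)
        )

    records: list[CandidateRecord] = []
    seen: set[str] = set()
    Z = np.array([h[0] for h in harvested])
    decoded = model.decode_batch(Z)
    for (x, p, run_seed, incumbent), out in zip(harvested, decoded):
        try:
            smiles = to_smiles(out, model.vocab.notation)
            valid = True
        except Exception:
            smiles, valid = "", False
        duplicate = valid and smiles in seen
        if valid:
            seen.add(smiles)
        records.append(
            CandidateRecord(
                latent=x, decoded=out, smiles=smiles, valid=valid,
                p_active=p, source_seed=run_seed, is_incumbent=incumbent,
                duplicate=duplicate,
            )
        )
    return records


def unique_library(records: Sequence[CandidateRecord]) -> list[CandidateRecord]:
    """The deduplicated valid library."""
    return [r for r in records if r.valid and not r.duplicate]


def library_validity(records: Sequence[CandidateRecord], incumbents_only: bool = False) -> float:
    """Fraction of valid decodes, over all probes or incumbents only."""
    pool = [r for r in records if r.is_incumbent] if incumbents_only else list(records)
    if not pool:
        return float("nan")
    return float(np.mean([r.valid for r in pool]))


def max_ring_size(mol: Chem.Mol) -> int:
    rings = mol.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


def apply_druglikeness_filters(
    records: Sequence[CandidateRecord],
    qed_min: float = 0.5,
    clogp_max: float = 8.0,
    max_ring: int = 7,
) -> list[CandidateRecord]:
    """Keep valid candidates with QED > qed_min, clogP < clogp_max and no
    ring larger than ``max_ring`` atoms; order is preserved and each
    record's ``properties``/``passed_filters`` fields are filled in."""
    kept = []
    for rec in records:
        if not rec.valid:
            rec.passed_filters = False
            continue
        mol = Chem.MolFromSmiles(rec.smiles)
        qed = QED.qed(mol)
        clogp = Crippen.MolLogP(mol)
        ring = max_ring_size(mol)
        rec.properties.update({"qed": qed, "clogp": clogp, "max_ring": ring})
        rec.passed_filters = qed > qed_min and clogp < clogp_max and ring <= max_ring
        if rec.passed_filters:
            kept.append(rec)
    return kept
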