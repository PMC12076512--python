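"""Latent-space activity models: K_i labeling, a nested cross-validated
classifier suite (SVM, random forest, gradient-boosted trees, MLP), and
the cosine-similarity distance-to-model applicability domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import DegenerateFoldError

ACTIVE_KI_NM = 100.0  # K_i <= 100 nM -> active
EXCLUDE_KI_NM = 10_000.0  # K_i >= 10 uM -> outside the modeling set


def label_activity(ki_nm: float) -> str:
    """Assign {active, inactive, excluded} from a K_i in nM."""
    if not (ki_nm > 0):
        raise ValueError(f"K_i must be positive, got {ki_nm}")
    if ki_nm >= EXCLUDE_KI_NM:
        return "excluded"
    if ki_nm <= ACTIVE_KI_NM:
        return "active"
    return "inactive"


@dataclass
class ActivityDataset:
    """Latent vectors with binary activity labels (1 = active)."""

    latents: np.ndarray
    labels: np.ndarray
    groups: Optional[np.ndarray] = None  # scaffold keys for grouped folds
    fingerprints: Optional[np.ndarray] = None

    def __post_init__(self):
        self.latents = np.asarray(self.latents, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.latents) != len(self.labels):
            raise ValueError("latents and labels must align")


DEFAULT_GRIDS: dict[str, dict] = {
    "svm": {"estimator__C": [1.0, 10.0], "estimator__gamma": ["scale"]},
    "rf": {"n_estimators": [200], "max_depth": [None, 8]},
    "xgb": {"n_estimators": [150], "max_depth": [3, 6]},
    "mlp": {"hidden_layer_sizes": [(64,), (128,)], "alpha": [1e-4]},
}


def _make_estimator(name: str, seed: int):
    if name == "svm":
        # probabilities via a calibrated decision function: the latent
        # search needs a continuous objective
        return CalibratedClassifierCV(SVC(random_state=seed), ensemble=False)
    if name == "rf":
        return RandomForestClassifier(random_state=seed)
    if name == "xgb":
        return XGBClassifier(
            random_state=seed, eval_metric="logloss", verbosity=0, n_jobs=1
        )
    if name == "mlp":
        return MLPClassifier(max_iter=800, random_state=seed)
    raise ValueError(f"unknown model {name!r}")


@dataclass
class CVReport:
    """Nested-CV metrics (mean and sd over outer folds) per model."""

    roc_auc: dict[str, tuple[float, float]] = field(default_factory=dict)
    accuracy: dict[str, tuple[float, float]] = field(default_factory=dict)
    fold_scores: dict[str, list[dict]] = field(default_factory=dict)
    best_params: dict[str, list[dict]] = field(default_factory=dict)


def _grouped_outer_folds(
    groups: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Seeded scaffold-grouped folds: shuffle unique groups, then assign
    greedily to the currently smallest fold, so scaffolds never straddle
    folds and sizes stay balanced."""
    uniq = np.array(sorted(set(groups.tolist())), dtype=object)
    rng = np.random.default_rng(seed)
    rng.shuffle(uniq)
    fold_of: dict = {}
    sizes = np.zeros(n_folds, dtype=int)
    counts = {g: int((groups == g).sum()) for g in uniq}
    for g in sorted(uniq, key=lambda g: -counts[g]):
        f = int(np.argmin(sizes))
        fold_of[g] = f
        sizes[f] += counts[g]
    assignment = np.array([fold_of[g] for g in groups])
    return [np.flatnonzero(assignment == f) for f in range(n_folds)]


def nested_cv(
    data: ActivityDataset,
    models: Sequence[str] = ("svm", "rf", "xgb", "mlp"),
    grids: Optional[dict[str, dict]] = None,
    seed: int = 0,
    n_outer: int = 5,
    n_inner: int = 5,
) -> CVReport:
    """Nested cross-validation: outer scaffold-grouped folds for evaluation
    and an inner grid search refit on each outer-train split.

    Raises :class:`~profis.errors.DegenerateFoldError` when an outer
    training split contains a single class.
    """
    grids = {**DEFAULT_GRIDS, **(grids or {})}
    Z, y = data.latents, data.labels
    groups = (
        data.groups
        if data.groups is not None
        else np.arange(len(y)).astype(str)  # singleton groups: plain split
    )
    folds = _grouped_outer_folds(np.asarray(groups), n_outer, seed)
    report = CVReport()
    for name in models:
        aucs, accs, fold_log, params_log = [], [], [], []
        for f, test_idx in enumerate(folds):
            train_idx = np.concatenate([folds[j] for j in range(n_outer) if j != f])
            y_tr = y[train_idx]
            if len(np.unique(y_tr)) < 2:
                raise DegenerateFoldError(f"outer fold {f} train split has one class")
            inner = KFold(n_splits=n_inner, shuffle=True, random_state=seed + f)
            search = GridSearchCV(
                _make_estimator(name, seed),
                grids[name],
                cv=inner,
                scoring="roc_auc",
                n_jobs=1,
            )
            search.fit(Z[train_idx], y_tr)
            prob = search.predict_proba(Z[test_idx])[:, 1]
            pred = (prob >= 0.5).astype(int)
            if len(np.unique(y[test_idx])) < 2:
                auc = np.nan
            else:
                auc = roc_auc_score(y[test_idx], prob)
            acc = accuracy_score(y[test_idx], pred)
            aucs.append(auc)
            accs.append(acc)
            fold_log.append({"fold": f, "roc_auc": auc, "accuracy": acc})
            params_log.append(search.best_params_)
        aucs_arr = np.array(aucs, dtype=float)
        report.roc_auc[name] = (float(np.nanmean(aucs_arr)), float(np.nanstd(aucs_arr)))
        report.accuracy[name] = (float(np.mean(accs)), float(np.std(accs)))
        report.fold_scores[name] = fold_log
        report.best_params[name] = params_log
    return report


def fit_classifier(
    data: ActivityDataset, model: str = "mlp", grid: Optional[dict] = None, seed: int = 0
):
    """Fit one classifier on the full dataset with an internal grid search
    (for downstream latent-space search)."""
    grid = grid if grid is not None else DEFAULT_GRIDS[model]
    search = GridSearchCV(
        _make_estimator(model, seed),
        grid,
        cv=KFold(n_splits=3, shuffle=True, random_state=seed),
        scoring="roc_auc",
        n_jobs=1,
    )
    search.fit(data.latents, data.labels)
    return search.best_estimator_


def distance_to_model(
    z: np.ndarray, train_Z: np.ndarray, n_neighbors: int = 3
) -> float:
    """Distance-oriented SCAvg: 1 minus the mean cosine similarity to the
    ``n_neighbors`` most-similar training vectors.  0 means the query sits
    on the training data; the theoretical range is [0, 2]."""
    z = np.asarray(z, dtype=float).ravel()
    train_Z = np.asarray(train_Z, dtype=float)
    if len(train_Z) < n_neighbors:
        raise ValueError("need at least n_neighbors training vectors")
    nz = np.linalg.norm(z)
    norms = np.linalg.norm(train_Z, axis=1)
    if nz == 0 or (norms == 0).any():
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    sims = train_Z @ z / (norms * nz)
    top = np.sort(sims)[-n_neighbors:]
    # rounding can push the result a hair outside [0, 2]
    return float(np.clip(1.0 - top.mean(), 0.0, 2.0))


DM_BINS = (0.05, 0.10, 0.15)


def dm_error_profile(
    predict_proba: Callable[[np.ndarray], np.ndarray],
    Z_eval: np.ndarray,
    y_eval: np.ndarray,
    train_Z: np.ndarray,
    bins: Sequence[float] = DM_BINS,
    n_neighbors: int = 3,
) -> list[dict]:
    """Bin evaluation points by distance-to-model and summarize the
    absolute prediction error and F1 per bin.

    Bins are half-open ``[low, high)`` over (0, *bins, inf).  Returns one
    dict per bin with keys ``lo, hi, n, median_abs_error, mean_abs_error,
    f1``; empty bins carry NaN statistics.
    """
    Z_eval = np.atleast_2d(np.asarray(Z_eval, dtype=float))
    y_eval = np.asarray(y_eval, dtype=int)
    dm = np.array([distance_to_model(z, train_Z, n_neighbors) for z in Z_eval])
    prob = np.asarray(predict_proba(Z_eval), dtype=float)
    if prob.ndim == 2:
        prob = prob[:, 1]
    err = np.abs(prob - y_eval)
    edges = [0.0, *bins, np.inf]
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (dm >= lo) & (dm < hi)
        n = int(in_bin.sum())
        if n == 0:
            out.append(
                {"lo": lo, "hi": hi, "n": 0, "median_abs_error": np.nan,
                 "mean_abs_error": np.nan, "f1": np.nan}
            )
            continue
        pred = (prob[in_bin] >= 0.5).astype(int)
        f1 = f1_score(y_eval[in_bin], pred, zero_division=0)
        out.append(
            {
                "lo": lo,
                "hi": hi,
                "n": n,
                "median_abs_error": float(np.median(err[in_bin])),
                "mean_abs_error": float(err[in_bin].mean()),
                "f1": float(f1),
            }
        )
    return out
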