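"""Latent search: bounds estimation, Bayesian optimization and filters."""

import numpy as np
import pytest

from profis.search import (
    CandidateRecord,
    SearchBox,
    apply_druglikeness_filters,
    bayesian_maximize,
    compute_bounds,
    max_ring_size,
)
from rdkit import Chem


class TestComputeBounds:
    def test_standard_normal_reference_gives_plus_minus_two(self):
        Z = np.random.default_rng(0).standard_normal((10000, 4))
        box = compute_bounds(Z, k=2.0)
        assert np.abs(box.low + 2).max() < 0.1
        assert np.abs(box.high - 2).max() < 0.1

    def test_constant_reference_widened_with_warning(self):
        Z = np.ones((10, 3))
        with pytest.warns(UserWarning):
            box = compute_bounds(Z, k=2.0, epsilon=0.01)
        assert np.allclose(box.high - box.low, 0.02)

    def test_k_zero_collapses_to_mean_before_widening(self):
        Z = np.random.default_rng(1).normal(2.0, 1.0, size=(500, 2))
        with pytest.warns(UserWarning):
            box = compute_bounds(Z, k=0.0, epsilon=0.5)
        center = (box.low + box.high) / 2
        assert center == pytest.approx(Z.mean(axis=0))

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            compute_bounds(np.ones((1, 3)))


def _quadratic(center):
    return lambda x: -float(((x - center) ** 2).sum())


class TestBayesianMaximize:
    def test_incumbent_matches_dense_grid_oracle(self):
        box = SearchBox(np.array([-3.0, -3.0]), np.array([3.0, 3.0]))
        center = np.array([1.2, -0.7])
        # independent oracle: dense grid search over the box
        grid = np.linspace(-3, 3, 121)
        gx, gy = np.meshgrid(grid, grid)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        oracle = pts[np.argmax([_quadratic(center)(p) for p in pts])]
        for seed in range(5):
            best_x, _, log = bayesian_maximize(
                _quadratic(center), box, init_points=4, n_iter=20,
                domain_reduction=True, seed=seed,
            )
            assert np.linalg.norm(best_x - oracle) < 0.5
            assert len(log) == 24

    def test_probes_stay_inside_the_active_box(self):
        box = SearchBox(np.array([-2.0, -2.0]), np.array([2.0, 2.0]))
        _, _, log = bayesian_maximize(
            _quadratic(np.zeros(2)), box, seed=1, domain_reduction=True
        )
        for rec in log:
            assert SearchBox(rec.box_low, rec.box_high).contains(rec.x)
            assert box.contains(rec.x)

    def test_domain_reduction_never_grows_the_box(self):
        box = SearchBox(np.array([-2.0, -2.0]), np.array([2.0, 2.0]))
        _, _, log = bayesian_maximize(
            _quadratic(np.zeros(2)), box, seed=2, domain_reduction=True
        )
        widths = [rec.box_high - rec.box_low for rec in log]
        for a, b in zip(widths, widths[1:]):
            assert (b <= a + 1e-12).all()

    def test_constant_objective_probe_count(self):
        box = SearchBox(np.array([0.0]), np.array([1.0]))
        _, best, log = bayesian_maximize(
            lambda x: 1.0, box, init_points=4, n_iter=6, seed=0
        )
        assert best == 1.0
        assert len(log) == 10

    def test_fixed_seed_gives_identical_probe_log(self):
        box = SearchBox(np.array([-1.0, -1.0]), np.array([1.0, 1.0]))
        logs = []
        for _ in range(2):
            _, _, log = bayesian_maximize(
                _quadratic(np.array([0.3, 0.3])), box, seed=11,
                domain_reduction=True,
            )
            logs.append([(rec.x.tolist(), rec.value) for rec in log])
        assert logs[0] == logs[1]

    def test_non_finite_probes_are_discarded_with_warning(self):
        box = SearchBox(np.array([0.0]), np.array([1.0]))
        calls = {"n": 0}

        def objective(x):
            calls["n"] += 1
            return np.nan if calls["n"] == 1 else float(x[0])

        with pytest.warns(UserWarning):
            _, best, log = bayesian_maximize(
                objective, box, init_points=2, n_iter=3, seed=0
            )
        assert np.isfinite(best)
        assert len(log) == 5


def _record(smiles):
    return CandidateRecord(
        latent=np.zeros(2), decoded=smiles, smiles=smiles, valid=True,
        p_active=1.0, source_seed=0, is_incumbent=False,
    )


class TestDruglikenessFilters:
    def test_eight_membered_ring_rejected(self):
        recs = [_record("C1CCCCCCC1")]
        assert apply_druglikeness_filters(recs) == []
        assert recs[0].properties["max_ring"] == 8

    def test_long_alkane_rejected_by_clogp(self):
        # additive lipophilicity pushes a C24 alkane far above the cutoff
        recs = [_record("C" * 24)]
        assert apply_druglikeness_filters(recs) == []
        assert recs[0].properties["clogp"] >= 8.0

    def test_surviving_records_satisfy_all_predicates_in_order(self):
        smiles = [
            "CC(=O)Nc1ccc(O)cc1",          # drug-like: passes
            "C1CCCCCCC1",                   # ring too large
            "c1ccc(-c2ccccc2)cc1",          # passes
        ]
        recs = [_record(s) for s in smiles]
        kept = apply_druglikeness_filters(recs)
        assert [r.smiles for r in kept] == [smiles[0], smiles[2]]
        for rec in kept:
            assert rec.properties["qed"] > 0.5
            assert rec.properties["clogp"] < 8.0
            assert rec.properties["max_ring"] <= 7

    def test_max_ring_size_helper(self):
        assert max_ring_size(Chem.MolFromSmiles("CCCC")) == 0
        assert max_ring_size(Chem.MolFromSmiles("C1CC1c1ccccc1")) == 6
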