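"""Analog generation, scaffold novelty, latent exploration and property
profiles, exercised on a small trained model."""

import numpy as np
import pytest

from profis.analogs import (
    generate_analogs,
    interpolate,
    latent_neighborhood,
    property_profile,
    scaffold_novelty,
)
from profis.chem import murcko_scaffold_smiles
from profis.fingerprints import compute_fingerprint, tanimoto_distance


class TestGenerateAnalogs:
    def test_zero_flips_reproduces_only_the_seed_reconstruction(self, toy_model):
        model = toy_model["model"]
        seed_smiles = toy_model["smiles"][0]
        report = generate_analogs(seed_smiles, model, n_copies=8, k_flips=0, seed=0)
        assert report.n_unique <= 1
        reconstruction = model.reconstruct(
            compute_fingerprint(seed_smiles, "ecfp4", 512).bits[None, :]
        )[0]
        if report.n_unique == 1:
            assert report.outputs[0].smiles == reconstruction

    def test_outputs_unique_and_valid(self, toy_model):
        report = generate_analogs(
            toy_model["smiles"][3], toy_model["model"], n_copies=50, k_flips=10,
            seed=1,
        )
        smiles = [o.smiles for o in report.outputs]
        assert len(smiles) == len(set(smiles))
        from rdkit import Chem

        assert all(Chem.MolFromSmiles(s) is not None for s in smiles)
        assert 0.0 <= report.validity_rate <= 1.0

    def test_distance_bookkeeping_matches_direct_computation(self, toy_model):
        model = toy_model["model"]
        seed_smiles = toy_model["smiles"][5]
        report = generate_analogs(seed_smiles, model, n_copies=30, k_flips=15, seed=2)
        seed_fp = compute_fingerprint(report.seed_smiles, "ecfp4", 512)
        for out in report.outputs:
            direct = tanimoto_distance(
                seed_fp, compute_fingerprint(out.smiles, "ecfp4", 512)
            )
            assert out.distance_to_seed == pytest.approx(direct)


class TestScaffoldNovelty:
    def test_known_scaffold_is_not_novel(self):
        ref = [murcko_scaffold_smiles("CCc1ccccc1")]
        scores = scaffold_novelty(["Cc1ccccc1"], ref)
        assert scores[0].min_distance == 0.0
        assert not scores[0].novel

    def test_unrelated_scaffold_is_novel(self):
        scores = scaffold_novelty(
            ["C1CCNCC1"], [murcko_scaffold_smiles("c1ccccc1")]
        )
        assert scores[0].min_distance > 0.25
        assert scores[0].novel

    def test_acyclic_molecule_flagged(self):
        scores = scaffold_novelty(["CCCCO"], ["c1ccccc1"])
        assert scores[0].acyclic

    def test_minimum_matches_brute_force_scan(self, corpus200):
        gen = [r.canonical_smiles for r in corpus200[:25]]
        refs = [r.scaffold_smiles for r in corpus200[100:140] if r.scaffold_smiles]
        scores = scaffold_novelty(gen, refs)
        ref_fps = [compute_fingerprint(s, "ecfp4", 2048) for s in refs]
        for smi, score in zip(gen, scores):
            scaffold = murcko_scaffold_smiles(smi)
            fp = compute_fingerprint(scaffold, "ecfp4", 2048)
            brute = min(tanimoto_distance(fp, rf) for rf in ref_fps)
            assert score.min_distance == pytest.approx(brute)

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            scaffold_novelty(["c1ccccc1"], [])


class TestLatentNeighborhood:
    def test_radius_zero_returns_seed_decode(self, toy_model):
        model = toy_model["model"]
        seed_smiles = toy_model["smiles"][0]
        hood = latent_neighborhood(seed_smiles, model, radii=[0.0], n_per_radius=4,
                                   seed=0)
        decoded = set(hood[0.0]["smiles"])
        assert len(decoded) <= 1

    def test_sampled_points_sit_on_the_requested_sphere(self, toy_model):
        model = toy_model["model"]
        seed_smiles = toy_model["smiles"][1]
        z0 = model.encode(
            compute_fingerprint(seed_smiles, "ecfp4", 512).bits, stochastic=False
        )
        hood = latent_neighborhood(seed_smiles, model, radii=[2.5], n_per_radius=6,
                                   seed=1)
        radii = np.linalg.norm(hood[2.5]["latents"] - z0, axis=1)
        assert radii == pytest.approx(2.5, abs=1e-9)

    def test_structural_drift_grows_with_radius(self, toy_model):
        model = toy_model["model"]
        seed_smiles = toy_model["smiles"][0]
        rhos = []
        for s in range(5):
            hood = latent_neighborhood(
                seed_smiles, model, radii=[0.5, 2.0, 5.0, 9.0], n_per_radius=12,
                seed=100 + s,
            )
            dists = [hood[r]["mean_distance"] for r in (0.5, 2.0, 5.0, 9.0)]
            from scipy.stats import spearmanr

            if len(set(dists)) > 1:
                rhos.append(spearmanr([0.5, 2.0, 5.0, 9.0], dists).statistic)
        assert np.mean(rhos) > 0


class TestInterpolate:
    def test_two_steps_are_the_endpoint_reconstructions(self, toy_model):
        model = toy_model["model"]
        a, b = toy_model["smiles"][0], toy_model["smiles"][50]
        path = interpolate(a, b, 2, model)
        assert path[0][1] == a
        assert path[1][1] == b

    def test_midpoint_is_the_mean_embedding(self, toy_model):
        model = toy_model["model"]
        a, b = toy_model["smiles"][2], toy_model["smiles"][40]
        path = interpolate(a, b, 3, model)
        assert path[1][0] == pytest.approx((path[0][0] + path[2][0]) / 2)

    def test_fewer_than_two_steps_rejected(self, toy_model):
        with pytest.raises(ValueError):
            interpolate("CCO", "CCN", 1, toy_model["model"])


class TestPropertyProfile:
    def test_known_descriptor_values(self):
        df = property_profile(["CCO", "c1ccccc1", "CCCCCC"]).set_index("smiles")
        assert df.loc["CCO", "hbd"] == 1
        assert df.loc["CCO", "hba"] == 1
        assert df.loc["c1ccccc1", "tpsa"] == 0.0
        assert df.loc["CCCCCC", "hbd"] == 0
        assert df.loc["CCCCCC", "hba"] == 0

    def test_descriptor_failure_flags_row(self):
        df = property_profile(["not_a_molecule", "CCO"])
        assert df["ok"].tolist() == [False, True]
        assert len(df) == 2
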