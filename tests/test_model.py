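"""The variational fingerprint-to-sequence network: loss analytics,
gradient correctness, decoding contracts and training behavior."""

import numpy as np
import pytest

from profis.codecs import TokenVocabulary, reference_vocabulary, tokenize
from profis.errors import ShapeError
from profis.fingerprints import compute_fingerprint
from profis.fixtures import FixtureSpec, make_corpus
from profis.model import (
    ModelConfig,
    ProfisModel,
    kl_divergence,
    kld_weight,
    sample_latents,
    toy_config,
)


@pytest.fixture(scope="module")
def micro():
    """A micro configuration for analytic and gradient tests."""
    vocab = TokenVocabulary("smiles", ["C", "N", "O", "=", "(", ")", "1"])
    cfg = ModelConfig(
        fp_len=12, vocab_size=vocab.size, latent_dim=4, encoder_hidden=(8, 8),
        gru_layers=3, gru_hidden=6, embed_dim=5, omega_dim=4, seq_len=9,
    )
    return ProfisModel(cfg, vocab, seed=0), cfg, vocab


class TestLossAnalytics:
    def test_kld_zero_at_the_prior(self):
        assert kl_divergence(np.zeros(32), np.zeros(32)) == 0.0

    def test_kld_closed_form_unit_mean(self):
        # mu = 1 in all 32 dims, sigma = 1: KLD = 0.5 * 32 = 16
        assert kl_divergence(np.ones(32), np.zeros(32)) == pytest.approx(16.0)

    def test_kld_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mu = rng.normal(size=8)
            lv = rng.normal(size=8)
            assert kl_divergence(mu, lv) >= 0.0

    def test_perfect_logits_give_zero_loss(self, micro):
        model, cfg, vocab = micro
        tgt = np.array([[3, 4, 5, vocab.end_idx, 0, 0, 0, 0, 0]])
        logits = np.full((1, 9, vocab.size), -1e9)
        for t, idx in enumerate(tgt[0]):
            logits[0, t, idx] = 1e9
        total, ce, kld = model.loss(logits, tgt, np.zeros(4), np.zeros(4), 0.1)
        assert total == pytest.approx(0.0, abs=1e-9)
        assert ce == pytest.approx(0.0, abs=1e-9)
        assert kld == 0.0


class TestKldWeight:
    def test_anneal_endpoints_and_midpoint(self):
        cfg = ModelConfig(fp_len=8, vocab_size=10)
        assert kld_weight(0, cfg) == 0.0
        assert kld_weight(25, cfg) == pytest.approx(0.05)
        assert kld_weight(50, cfg) == pytest.approx(0.1)
        assert kld_weight(500, cfg) == pytest.approx(0.1)

    def test_monotone_nondecreasing(self):
        cfg = ModelConfig(fp_len=8, vocab_size=10)
        weights = [kld_weight(e, cfg) for e in range(80)]
        assert all(b >= a for a, b in zip(weights, weights[1:]))


class TestGradients:
    def test_backprop_matches_finite_differences(self, micro):
        model, cfg, vocab = micro
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (3, cfg.fp_len)).astype(float)
        S = np.zeros((3, cfg.seq_len), dtype=np.int64)
        for b in range(3):
            n = rng.integers(2, 6)
            S[b, :n] = rng.integers(3, vocab.size, n)
            S[b, n] = vocab.end_idx
        eps = rng.standard_normal((3, cfg.latent_dim))
        _, _, _, grads = model._forward_backward(X, S, eps, 0.1)
        for name in sorted(model.params):
            flat = model.params[name].reshape(-1)
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                h, old = 1e-6, flat[i]
                flat[i] = old + h
                up, *_ = model._forward_backward(X, S, eps, 0.1)
                flat[i] = old - h
                dn, *_ = model._forward_backward(X, S, eps, 0.1)
                flat[i] = old
                num = (up - dn) / (2 * h)
                ana = grads[name].reshape(-1)[i]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-7), name


class TestEncode:
    def test_mean_path_is_deterministic(self, micro):
        model, cfg, _ = micro
        fp = np.ones(cfg.fp_len)
        assert np.array_equal(model.encode(fp), model.encode(fp))

    def test_stochastic_draws_are_seeded(self, micro):
        model, cfg, _ = micro
        fp = np.ones(cfg.fp_len)
        a = model.encode(fp, stochastic=True, seed=5)
        b = model.encode(fp, stochastic=True, seed=5)
        c = model.encode(fp, stochastic=True, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_wrong_length_raises(self, micro):
        model, _, _ = micro
        with pytest.raises(ShapeError):
            model.encode(np.ones(7))


class TestDecode:
    def test_greedy_is_deterministic(self, micro):
        model, cfg, _ = micro
        z = np.linspace(-1, 1, cfg.latent_dim)
        assert model.decode(z) == model.decode(z)

    def test_output_never_exceeds_sequence_length(self, micro):
        model, cfg, vocab = micro
        rng = np.random.default_rng(2)
        for z in rng.normal(size=(10, cfg.latent_dim)):
            from profis.codecs import lex

            out = model.decode(z)
            assert len(lex(out, "smiles")) <= cfg.seq_len if out else True

    def test_sampled_decode_is_seeded(self, micro):
        model, cfg, _ = micro
        z = np.zeros(cfg.latent_dim)
        a = model.decode(z, mode="sample", temperature=1.0, seed=3)
        b = model.decode(z, mode="sample", temperature=1.0, seed=3)
        assert a == b


class TestTraining:
    def test_loss_log_decomposition(self, overfit_model):
        for entry in overfit_model["log"]:
            assert entry["total"] == pytest.approx(
                entry["ce"] + entry["beta_t"] * entry["kld"]
            )

    def test_same_seed_reproduces_loss_log(self, micro):
        _, cfg, vocab = micro
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, (6, cfg.fp_len)).astype(float)
        S = np.zeros((6, cfg.seq_len), dtype=np.int64)
        S[:, 0] = 3
        S[:, 1] = vocab.end_idx
        logs = []
        for _ in range(2):
            m = ProfisModel(cfg, vocab, seed=9)
            logs.append(m.fit(X, S, epochs=4, seed=11))
        assert logs[0] == logs[1]

    def test_single_molecule_overfit_reproduces_training_string(self, smiles_vocab):
        rec = make_corpus(FixtureSpec(n_molecules=1, seed=7))[0]
        X = np.array([compute_fingerprint(rec.canonical_smiles, "ecfp4", 512).bits],
                     float)
        S = np.array([tokenize(rec.canonical_smiles, smiles_vocab).indices])
        cfg = toy_config(512, smiles_vocab.size, encoder_hidden=(64, 64), batch_size=1)
        model = ProfisModel(cfg, smiles_vocab, seed=0)
        model.fit(X, S, epochs=300, seed=2)
        assert model.reconstruct(X)[0] == rec.canonical_smiles

    def test_annealing_beats_frozen_beta_on_final_reconstruction(
        self, corpus50, smiles_vocab
    ):
        smiles = [r.canonical_smiles for r in corpus50]
        X = np.array(
            [compute_fingerprint(s, "ecfp4", 512).bits for s in smiles], float
        )
        S = np.array([tokenize(s, smiles_vocab).indices for s in smiles])
        final_ce = {}
        for label, anneal in (("annealed", 50), ("frozen", 0)):
            cfg = toy_config(512, smiles_vocab.size, beta=0.02, anneal_epochs=anneal)
            m = ProfisModel(cfg, smiles_vocab, seed=0)
            log = m.fit(X, S, epochs=120, seed=1)
            final_ce[label] = log[-1]["ce"]
        assert final_ce["annealed"] < final_ce["frozen"]

    def test_empty_dataset_raises(self, micro):
        model, cfg, _ = micro
        with pytest.raises(ValueError):
            model.fit(np.empty((0, cfg.fp_len)), np.empty((0, cfg.seq_len)), 1)


class TestSampleLatents:
    def test_prior_moments(self):
        Z = sample_latents("prior", 1000, 8, seed=0)
        assert np.abs(Z.mean(axis=0)).max() < 4 / np.sqrt(1000) + 0.05

    def test_degenerate_posterior_collapses_to_point(self):
        train_Z = np.tile([1.0, -2.0, 3.0], (10, 1))
        Z = sample_latents("aggregated_posterior", 5, 3, train_Z, seed=1)
        assert np.allclose(Z, train_Z[0])

    def test_posterior_requires_embeddings(self):
        with pytest.raises(ValueError):
            sample_latents("aggregated_posterior", 5, 3, None)

    def test_seeded(self):
        a = sample_latents("prior", 4, 6, seed=2)
        b = sample_latents("prior", 4, 6, seed=2)
        assert np.array_equal(a, b)


class TestCheckpoint:
    def test_save_load_round_trip(self, micro, tmp_path):
        model, cfg, _ = micro
        model.save(tmp_path / "ckpt")
        loaded = ProfisModel.load(tmp_path / "ckpt")
        z = np.linspace(-1, 1, cfg.latent_dim)
        assert loaded.decode(z) == model.decode(z)
        assert loaded.vocab.tokens == model.vocab.tokens
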