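"""The fingerprint-to-sequence network: a stochastic fingerprint encoder, a
stacked GRU sequence decoder, the two-term loss with cosine KLD annealing,
and the training loop.

The architecture maps a binary fingerprint x to a diagonal Gaussian over a
32-dimensional latent space (two ReLU layers, then parallel mean and
log-variance heads).  A latent sample z = mu + sigma * eps conditions an
autoregressive GRU stack: at every timestep the GRU input is omega(z)
concatenated with the embedding of the previous token (start marker at the
first step), all hidden states start at zero, and an affine layer with
softmax maps the top GRU output to token probabilities.

Everything is implemented in NumPy (float64) with hand-written
backpropagation through time and an Adam optimizer, which keeps the model
fully deterministic under a seed and dependency-free.  The reference
configuration matches the published architecture (latent 32, encoder
hidden (1024, 1024), 3 GRU layers of width 512, sequence length 100,
beta = 0.1, 50 annealing epochs); every dimension scales down for tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .codecs import SEQ_LEN, TokenSequence, TokenVocabulary, detokenize
from .errors import NotReadyError, ShapeError


@dataclass
class ModelConfig:
    """Hyperparameters of the network and its training loop."""

    fp_len: int
    vocab_size: int
    notation: str = "smiles"
    fp_type: str = "ecfp4"
    latent_dim: int = 32
    encoder_hidden: tuple[int, int] = (1024, 1024)
    gru_layers: int = 3
    gru_hidden: int = 512
    embed_dim: int = 64
    omega_dim: int = 128
    seq_len: int = SEQ_LEN
    beta: float = 0.1
    anneal_epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 64
    grad_clip: float = 5.0


def toy_config(
    fp_len: int,
    vocab_size: int,
    notation: str = "smiles",
    fp_type: str = "ecfp4",
    **overrides,
) -> ModelConfig:
    """Scaled-down configuration for small corpora (tests, demos).

    The architecture keeps the reference latent width (32) but shrinks the
    encoder and GRU, and scales the KLD weight down to beta = 0.001: the
    per-molecule information budget the latent must carry grows as the
    corpus shrinks, so the regularization weight balanced for a
    million-molecule corpus collapses the posterior on a few hundred
    molecules.
    """
    defaults = dict(
        latent_dim=32,
        encoder_hidden=(256, 256),
        gru_layers=3,
        gru_hidden=128,
        embed_dim=32,
        omega_dim=32,
        beta=0.001,
        learning_rate=3e-3,
        batch_size=50,
    )
    defaults.update(overrides)
    return ModelConfig(
        fp_len=fp_len, vocab_size=vocab_size, notation=notation,
        fp_type=fp_type, **defaults,
    )


def kld_weight(epoch: int, cfg: ModelConfig) -> float:
    """Cosine annealing of the KLD weight: a half-cosine ramp from 0 to
    beta over the first ``anneal_epochs`` epochs, constant afterwards."""
    if epoch >= cfg.anneal_epochs:
        return cfg.beta
    return cfg.beta * 0.5 * (1.0 - np.cos(np.pi * epoch / cfg.anneal_epochs))


def kl_divergence(mean: np.ndarray, log_var: np.ndarray) -> float:
    """KL(q || N(0, I)) summed over latent dimensions, averaged over the
    batch: 0.5 * sum(mu^2 + sigma^2 - log sigma^2 - 1)."""
    mean = np.atleast_2d(mean)
    log_var = np.atleast_2d(log_var)
    per_sample = 0.5 * (mean**2 + np.exp(log_var) - log_var - 1.0).sum(axis=1)
    return float(per_sample.mean())


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


class ProfisModel:
    """Fingerprint encoder + GRU sequence decoder."""

    def __init__(self, cfg: ModelConfig, vocab: TokenVocabulary, seed: int = 0):
        if cfg.vocab_size != vocab.size:
            raise ValueError("config vocab_size disagrees with the vocabulary")
        self.cfg = cfg
        self.vocab = vocab
        self.params: dict[str, np.ndarray] = {}
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0
        self._init_params(np.random.default_rng(seed))

    # ------------------------------------------------------------------
    def _init_params(self, rng) -> None:
        c = self.cfg
        p = self.params
        h1, h2 = c.encoder_hidden
        p["We1"] = _glorot(rng, (c.fp_len, h1)); p["be1"] = np.zeros(h1)
        p["We2"] = _glorot(rng, (h1, h2)); p["be2"] = np.zeros(h2)
        p["Wmu"] = _glorot(rng, (h2, c.latent_dim)); p["bmu"] = np.zeros(c.latent_dim)
        p["Wlv"] = _glorot(rng, (h2, c.latent_dim)); p["blv"] = np.zeros(c.latent_dim)
        p["Wom"] = _glorot(rng, (c.latent_dim, c.omega_dim))
        p["bom"] = np.zeros(c.omega_dim)
        p["Emb"] = 0.1 * rng.standard_normal((c.vocab_size, c.embed_dim))
        gin = c.omega_dim + c.embed_dim
        for l in range(c.gru_layers):
            isz = gin if l == 0 else c.gru_hidden
            for gate in ("z", "r", "c"):
                p[f"W{gate}{l}"] = _glorot(rng, (isz, c.gru_hidden))
                p[f"U{gate}{l}"] = _glorot(rng, (c.gru_hidden, c.gru_hidden))
                p[f"b{gate}{l}"] = np.zeros(c.gru_hidden)
        p["Wps"] = _glorot(rng, (c.gru_hidden, c.vocab_size))
        p["bps"] = np.zeros(c.vocab_size)

    # ------------------------------------------------------------------
    # encoder
    def _encode_stats(self, X: np.ndarray):
        p = self.params
        H1 = np.maximum(X @ p["We1"] + p["be1"], 0.0)
        H2 = np.maximum(H1 @ p["We2"] + p["be2"], 0.0)
        mu = H2 @ p["Wmu"] + p["bmu"]
        lv = H2 @ p["Wlv"] + p["blv"]
        return H1, H2, mu, lv

    def encode(
        self,
        fp,
        stochastic: bool = False,
        seed: Optional[int] = None,
    ) -> np.ndarray:
        """Embed fingerprint(s).  ``stochastic=True`` draws a reparametrized
        sample z = mu + sigma * eps; otherwise returns the mean mu."""
        X = fp.bits if hasattr(fp, "bits") else np.asarray(fp)
        X = np.atleast_2d(X).astype(float)
        if X.shape[1] != self.cfg.fp_len:
            raise ShapeError(
                f"fingerprint length {X.shape[1]} != configured {self.cfg.fp_len}"
            )
        _, _, mu, lv = self._encode_stats(X)
        if stochastic:
            rng = np.random.default_rng(seed)
            z = mu + np.exp(0.5 * lv) * rng.standard_normal(mu.shape)
        else:
            z = mu
        return z[0] if z.shape[0] == 1 else z

    # ------------------------------------------------------------------
    # decoder
    def _gru_step(self, l: int, x: np.ndarray, h: np.ndarray):
        p = self.params
        zg = _sigmoid(x @ p[f"Wz{l}"] + h @ p[f"Uz{l}"] + p[f"bz{l}"])
        r = _sigmoid(x @ p[f"Wr{l}"] + h @ p[f"Ur{l}"] + p[f"br{l}"])
        hh = np.tanh(x @ p[f"Wc{l}"] + (r * h) @ p[f"Uc{l}"] + p[f"bc{l}"])
        h_new = (1.0 - zg) * h + zg * hh
        return h_new, (x, h, zg, r, hh)

    def decode(
        self,
        z: np.ndarray,
        mode: str = "greedy",
        temperature: float = 1.0,
        seed: Optional[int] = None,
    ) -> str:
        """Autoregressive generation from one latent vector; returns the
        detokenized string in the model's notation."""
        return self.decode_batch(np.atleast_2d(z), mode, temperature, seed)[0]

    def decode_batch(
        self,
        Z: np.ndarray,
        mode: str = "greedy",
        temperature: float = 1.0,
        seed: Optional[int] = None,
    ) -> list[str]:
        if not self.params:
            raise NotReadyError("model has no parameters")
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.cfg.latent_dim:
            raise ShapeError(f"latent dim {Z.shape[1]} != {self.cfg.latent_dim}")
        p, c, v = self.params, self.cfg, self.vocab
        B = Z.shape[0]
        rng = np.random.default_rng(seed)
        u = Z @ p["Wom"] + p["bom"]
        h = [np.zeros((B, c.gru_hidden)) for _ in range(c.gru_layers)]
        prev = np.full(B, v.start_idx, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        out = np.full((B, c.seq_len), v.pad_idx, dtype=np.int64)
        for t in range(c.seq_len):
            x = np.concatenate([u, p["Emb"][prev]], axis=1)
            for l in range(c.gru_layers):
                h[l], _ = self._gru_step(l, x, h[l])
                x = h[l]
            logits = h[-1] @ p["Wps"] + p["bps"]
            logits[:, v.pad_idx] = -np.inf
            logits[:, v.start_idx] = -np.inf
            if mode == "greedy":
                nxt = logits.argmax(axis=1)
            elif mode == "sample":
                scaled = logits / max(temperature, 1e-8)
                scaled -= scaled.max(axis=1, keepdims=True)
                prob = np.exp(scaled)
                prob /= prob.sum(axis=1, keepdims=True)
                cum = prob.cumsum(axis=1)
                draws = rng.random((B, 1))
                nxt = (draws < cum).argmax(axis=1)
            else:
                raise ValueError(f"unknown decode mode {mode!r}")
            nxt = np.where(done, v.pad_idx, nxt)
            out[:, t] = nxt
            done |= nxt == v.end_idx
            if done.all():
                break
            prev = np.where(done, v.end_idx, nxt)
        return [detokenize(TokenSequence(row, v.notation), v) for row in
                (np.pad(out, ((0, 0), (0, SEQ_LEN - out.shape[1])))
                 if out.shape[1] < SEQ_LEN else out)]

    # ------------------------------------------------------------------
    # loss and training
    def _forward_backward(self, X, S, eps, beta_t):
        """One training step's loss and gradients (teacher forcing)."""
        p, c, v = self.params, self.cfg, self.vocab
        B = X.shape[0]
        # trim to the longest effective sequence in the batch
        lengths = (S != v.pad_idx).sum(axis=1)
        T = int(lengths.max())
        tgt = S[:, :T]
        inp = np.concatenate(
            [np.full((B, 1), v.start_idx, dtype=np.int64), tgt[:, :-1]], axis=1
        )
        mask = (tgt != v.pad_idx).astype(float)
        n_tok = mask.sum()

        H1, H2, mu, lv = self._encode_stats(X)
        sigma = np.exp(0.5 * lv)
        z = mu + sigma * eps
        u = z @ p["Wom"] + p["bom"]

        caches = [[None] * T for _ in range(c.gru_layers)]
        h = [np.zeros((B, c.gru_hidden)) for _ in range(c.gru_layers)]
        tops = np.empty((T, B, c.gru_hidden))
        x0s = np.empty((T, B, c.omega_dim + c.embed_dim))
        for t in range(T):
            x = np.concatenate([u, p["Emb"][inp[:, t]]], axis=1)
            x0s[t] = x
            for l in range(c.gru_layers):
                h[l], caches[l][t] = self._gru_step(l, x, h[l])
                x = h[l]
            tops[t] = h[-1]

        logits = tops @ p["Wps"] + p["bps"]  # [T,B,V]
        logits_sh = logits - logits.max(axis=2, keepdims=True)
        exp = np.exp(logits_sh)
        prob = exp / exp.sum(axis=2, keepdims=True)
        tgt_t = tgt.T  # [T,B]
        idx_t, idx_b = np.meshgrid(np.arange(T), np.arange(B), indexing="ij")
        logp = np.log(prob[idx_t, idx_b, tgt_t] + 1e-300)
        ce = float(-(logp * mask.T).sum() / n_tok)
        kld = kl_divergence(mu, lv)
        total = ce + beta_t * kld

        # ---- backward
        grads = {k: np.zeros_like(val) for k, val in p.items()}
        dlogits = prob.copy()
        dlogits[idx_t, idx_b, tgt_t] -= 1.0
        dlogits *= (mask.T / n_tok)[:, :, None]
        grads["Wps"] = np.einsum("tbm,tbv->mv", tops, dlogits)
        grads["bps"] = dlogits.sum(axis=(0, 1))
        dtops = dlogits @ p["Wps"].T  # [T,B,m]

        dh_carry = [np.zeros((B, c.gru_hidden)) for _ in range(c.gru_layers)]
        du = np.zeros((B, c.omega_dim))
        dEmb = grads["Emb"]
        for t in range(T - 1, -1, -1):
            incoming = dtops[t]
            for l in range(c.gru_layers - 1, -1, -1):
                dh = dh_carry[l] + incoming
                x, h_prev, zg, r, hh = caches[l][t]
                dzg = dh * (hh - h_prev)
                dhh = dh * zg
                dh_prev = dh * (1.0 - zg)
                dhh_pre = dhh * (1.0 - hh**2)
                grads[f"Wc{l}"] += x.T @ dhh_pre
                grads[f"Uc{l}"] += (r * h_prev).T @ dhh_pre
                grads[f"bc{l}"] += dhh_pre.sum(axis=0)
                drh = dhh_pre @ p[f"Uc{l}"].T
                dr = drh * h_prev
                dh_prev += drh * r
                dzg_pre = dzg * zg * (1.0 - zg)
                dr_pre = dr * r * (1.0 - r)
                grads[f"Wz{l}"] += x.T @ dzg_pre
                grads[f"Uz{l}"] += h_prev.T @ dzg_pre
                grads[f"bz{l}"] += dzg_pre.sum(axis=0)
                grads[f"Wr{l}"] += x.T @ dr_pre
                grads[f"Ur{l}"] += h_prev.T @ dr_pre
                grads[f"br{l}"] += dr_pre.sum(axis=0)
                dx = dzg_pre @ p[f"Wz{l}"].T + dr_pre @ p[f"Wr{l}"].T + dhh_pre @ p[f"Wc{l}"].T
                dh_prev += dzg_pre @ p[f"Uz{l}"].T + dr_pre @ p[f"Ur{l}"].T
                dh_carry[l] = dh_prev
                incoming = dx
            du += incoming[:, : c.omega_dim]
            np.add.at(dEmb, inp[:, t], incoming[:, c.omega_dim:])

        grads["Wom"] = z.T @ du
        grads["bom"] = du.sum(axis=0)
        dz = du @ p["Wom"].T
        # KLD gradients (batch-mean)
        dmu = dz + beta_t * mu / B
        dlv = dz * eps * 0.5 * sigma + beta_t * 0.5 * (np.exp(lv) - 1.0) / B
        grads["Wmu"] = H2.T @ dmu
        grads["bmu"] = dmu.sum(axis=0)
        grads["Wlv"] = H2.T @ dlv
        grads["blv"] = dlv.sum(axis=0)
        dH2 = (dmu @ p["Wmu"].T + dlv @ p["Wlv"].T) * (H2 > 0)
        grads["We2"] = H1.T @ dH2
        grads["be2"] = dH2.sum(axis=0)
        dH1 = dH2 @ p["We2"].T * (H1 > 0)
        grads["We1"] = X.T @ dH1
        grads["be1"] = dH1.sum(axis=0)
        return total, ce, kld, grads

    def _adam_update(self, grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        scale = min(1.0, c.grad_clip / (norm + 1e-12))
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for k, g in grads.items():
            g = g * scale
            m = self._adam_m.setdefault(k, np.zeros_like(g))
            v = self._adam_v.setdefault(k, np.zeros_like(g))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= c.learning_rate * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        X: np.ndarray,
        S: np.ndarray,
        epochs: int,
        seed: int = 0,
        start_epoch: int = 0,
        callback=None,
    ) -> list[dict]:
        """Train with teacher forcing; returns the per-epoch loss log with
        entries ``{epoch, ce, kld, beta_t, total}``."""
        X = np.asarray(X, dtype=float)
        S = np.asarray(S, dtype=np.int64)
        if len(X) == 0:
            raise ValueError("empty dataset")
        if X.shape[1] != self.cfg.fp_len:
            raise ShapeError("fingerprint length mismatch")
        rng = np.random.default_rng(seed)
        log: list[dict] = []
        n = len(X)
        bs = min(self.cfg.batch_size, n)
        for epoch in range(start_epoch, start_epoch + epochs):
            beta_t = kld_weight(epoch, self.cfg)
            order = rng.permutation(n)
            ce_sum = kld_sum = 0.0
            n_batches = 0
            for i in range(0, n, bs):
                idx = order[i : i + bs]
                eps = rng.standard_normal((len(idx), self.cfg.latent_dim))
                total, ce, kld, grads = self._forward_backward(
                    X[idx], S[idx], eps, beta_t
                )
                if not np.isfinite(total):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch} (ce={ce}, kld={kld})"
                    )
                self._adam_update(grads)
                ce_sum += ce
                kld_sum += kld
                n_batches += 1
            ce_m, kld_m = ce_sum / n_batches, kld_sum / n_batches
            log.append(
                {
                    "epoch": epoch,
                    "ce": ce_m,
                    "kld": kld_m,
                    "beta_t": beta_t,
                    "total": ce_m + beta_t * kld_m,
                }
            )
            if callback is not None:
                callback(log[-1])
        return log

    def loss(
        self,
        token_logits: np.ndarray,
        target: np.ndarray,
        mean: np.ndarray,
        log_var: np.ndarray,
        beta_t: float,
    ) -> tuple[float, float, float]:
        """Evaluate (total, reconstruction, kld) for given logits/targets.

        Cross-entropy is averaged over non-pad positions; the KLD is the
        closed form against the standard normal."""
        logits = np.asarray(token_logits, dtype=float)
        tgt = np.asarray(target, dtype=np.int64)
        mask = tgt != self.vocab.pad_idx
        shifted = logits - logits.max(axis=-1, keepdims=True)
        logp = shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
        picked = np.take_along_axis(logp, tgt[..., None], axis=-1)[..., 0]
        ce = float(-(picked * mask).sum() / max(mask.sum(), 1))
        kld = kl_divergence(mean, log_var)
        return ce + beta_t * kld, ce, kld

    # ------------------------------------------------------------------
    def reconstruct(self, X: np.ndarray) -> list[str]:
        """Greedy decode of the deterministic (mean) embeddings."""
        Z = np.atleast_2d(self.encode(X, stochastic=False))
        return self.decode_batch(Z)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {
            "config": asdict(self.cfg),
            "notation": self.vocab.notation,
            "tokens": self.vocab.tokens,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "ProfisModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg_d = meta["config"]
        cfg_d["encoder_hidden"] = tuple(cfg_d["encoder_hidden"])
        cfg = ModelConfig(**cfg_d)
        vocab = TokenVocabulary(meta["notation"], meta["tokens"])
        model = cls(cfg, vocab)
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k] for k in data.files}
        return model


def train(
    X: np.ndarray,
    S: np.ndarray,
    cfg: ModelConfig,
    vocab: TokenVocabulary,
    epochs: int,
    seed: int = 0,
) -> tuple[ProfisModel, list[dict]]:
    """Train a fresh model on (fingerprints, token sequences)."""
    model = ProfisModel(cfg, vocab, seed=seed)
    log = model.fit(X, S, epochs=epochs, seed=seed + 1)
    return model, log


def sample_latents(
    mode: str,
    n: int,
    latent_dim: int,
    train_Z: Optional[np.ndarray] = None,
    seed: int = 0,
) -> np.ndarray:
    """Draw latent vectors from the prior N(0, I) or from a diagonal normal
    moment-matched to the training embeddings (aggregated posterior)."""
    rng = np.random.default_rng(seed)
    if mode == "prior":
        return rng.standard_normal((n, latent_dim))
    if mode == "aggregated_posterior":
        if train_Z is None:
            raise ValueError("aggregated_posterior requires training embeddings")
        train_Z = np.asarray(train_Z, dtype=float)
        mu = train_Z.mean(axis=0)
        sd = train_Z.std(axis=0)
        return mu + sd * rng.standard_normal((n, len(mu)))
    raise ValueError(f"unknown sampling mode {mode!r}")
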