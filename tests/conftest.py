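"""Shared fixtures: synthetic corpora and two small trained models.

The session-scoped models are intentionally tiny but fully trained, so the
generative tests (reconstruction, analog noising, latent search) exercise
real learned behavior rather than mocks.
"""

import numpy as np
import pytest

from profis.codecs import reference_vocabulary, tokenize
from profis.fingerprints import compute_fingerprint
from profis.fixtures import FixtureSpec, make_activity_dataset, make_corpus
from profis.model import ProfisModel, toy_config


@pytest.fixture(scope="session")
def smiles_vocab():
    return reference_vocabulary("smiles")


@pytest.fixture(scope="session")
def corpus50():
    return make_corpus(FixtureSpec(n_molecules=50, seed=7))


@pytest.fixture(scope="session")
def corpus200():
    return make_corpus(FixtureSpec(n_molecules=200, seed=3))


def _featurize(records, vocab):
    smiles = [r.canonical_smiles for r in records]
    X = np.array([compute_fingerprint(s, "ecfp4", 512).bits for s in smiles], float)
    S = np.array([tokenize(s, vocab).indices for s in smiles])
    return smiles, X, S


@pytest.fixture(scope="session")
def overfit_model(corpus50, smiles_vocab):
    """A tiny model trained to memorize 50 molecules (200 epochs)."""
    smiles, X, S = _featurize(corpus50, smiles_vocab)
    cfg = toy_config(512, smiles_vocab.size)
    model = ProfisModel(cfg, smiles_vocab, seed=0)
    log = model.fit(X, S, epochs=200, seed=1)
    return {"model": model, "smiles": smiles, "X": X, "S": S, "log": log}


@pytest.fixture(scope="session")
def activity_data120():
    """Labeled fixture set with the sulfonamide activity rule."""
    data = make_activity_dataset(FixtureSpec(n_molecules=120, seed=11))
    records = [r for r, _ in data]
    ki = np.array([k for _, k in data])
    return records, ki


@pytest.fixture(scope="session")
def toy_model(activity_data120, smiles_vocab):
    """A small generative model trained on the 120-molecule labeled set,
    shared by the analog, neighborhood and search tests."""
    records, ki = activity_data120
    smiles, X, S = _featurize(records, smiles_vocab)
    cfg = toy_config(512, smiles_vocab.size)
    model = ProfisModel(cfg, smiles_vocab, seed=0)
    model.fit(X, S, epochs=250, seed=1)
    Z = np.atleast_2d(model.encode(X, stochastic=False))
    y = (ki <= 100.0).astype(int)
    return {
        "model": model,
        "smiles": smiles,
        "X": X,
        "Z": Z,
        "y": y,
        "records": records,
    }
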