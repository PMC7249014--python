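"""Shared fixtures: synthetic corpora, trained models, reference molecules.

Heavy artifacts (trained DCN, BBB models) are session-scoped so the suite
trains each model once.
"""

from __future__ import annotations

import numpy as np
import pytest

import litmine as lm
from litmine.dcn import DCNConfig, train
from litmine.synthetic import make_panel_bbb_training_set
from litmine.triage import train_bbb_svm

# Reference structures: zileuton from its systematic name
# (+-)-1-(1-benzo[b]thien-2-ylethyl)-1-hydroxyurea, and TCDD from
# 2,3,7,8-tetrachlorodibenzo-p-dioxin.
ZILEUTON_SMILES = "CC(c1cc2ccccc2s1)N(O)C(N)=O"
TCDD_SMILES = "O1c2cc(Cl)c(Cl)cc2Oc2cc(Cl)c(Cl)cc12"


@pytest.fixture(scope="session")
def encoder_config() -> lm.EncoderConfig:
    return lm.EncoderConfig()


@pytest.fixture(scope="session")
def planted_corpus():
    """Fully planted benchmark corpus: 20 documents, one answer each."""
    return lm.make_corpus(lm.CorpusSpec(n_docs=20, plant_probability=1.0, seed=42))


@pytest.fixture(scope="session")
def mixed_corpus():
    """Partially planted corpus (some documents have no true answer)."""
    return lm.make_corpus(lm.CorpusSpec(n_docs=20, plant_probability=0.8, seed=42))


@pytest.fixture(scope="session")
def trained_dcn(mixed_corpus):
    """DCN trained to convergence on relevance pairs from the mixed corpus."""
    corpus, gold = mixed_corpus
    pairs = lm.make_relevance_pairs(corpus, gold, n_irrelevant_per_doc=3, seed=42)
    return train(pairs, DCNConfig(seed=42)), pairs


@pytest.fixture(scope="session")
def panel_bbb_model():
    """Linear SVM fitted on the structure panel's fingerprints with
    TPSA-heuristic labels."""
    X, y = make_panel_bbb_training_set()
    return train_bbb_svm(X, y, C=10.0, seed=0)


@pytest.fixture(scope="session")
def dcn_heldout_accuracy() -> float:
    """Best-split-threshold accuracy of a DCN trained on 150 of the 200
    seed-1 synthetic relevance pairs, evaluated on the held-out 50."""
    from litmine.dcn import relevance_score

    corpus, gold = lm.make_corpus(lm.CorpusSpec(n_docs=50, seed=1))
    pairs = lm.make_relevance_pairs(corpus, gold, n_irrelevant_per_doc=3, seed=1)
    idx = np.random.default_rng(1).permutation(len(pairs))
    n_tr = int(0.75 * len(pairs))
    tr = [pairs[i] for i in idx[:n_tr]]
    te = [pairs[i] for i in idx[n_tr:]]
    model = train(tr, DCNConfig(seed=1))
    scores = np.array(
        [relevance_score(p.question_embedding, p.answer_embedding, model) for p in te]
    )
    labels = np.array([p.label for p in te])
    return float(max(((scores >= t) == labels).mean() for t in np.unique(scores)))


@pytest.fixture(scope="session")
def bbb_recovery_accuracy() -> float:
    """Held-out accuracy of the BBB SVM against the generating rule on the
    default (seed-3) synthetic set, 75/25 split, C by cross-validation."""
    spec = lm.BBBSpec()
    X, y, (w, b) = lm.make_bbb_dataset(spec)
    clean = np.where(X @ w + b >= 0, 1, -1)
    idx = np.random.default_rng(spec.seed).permutation(len(y))
    n_tr = int(0.75 * len(y))
    tr, te = idx[:n_tr], idx[n_tr:]
    model = train_bbb_svm(X[tr], y[tr], n_bits=spec.n_bits, C=None, seed=spec.seed)
    pred = np.where(X[te] @ model.weights + model.bias > 0, 1, -1)
    return float((pred == clean[te]).mean())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
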