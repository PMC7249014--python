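"""Synthetic study-condition generators.

Every pipeline stage is exercised without downloads by generating:

* corpora of background-vocabulary filler sentences with planted
  compound-answer sentences that share content tokens with the canonical
  question (emulating a literature corpus where a handful of sentences
  actually answer the question);
* labeled question/answer relevance pairs for the differential
  convolution network;
* noisy linearly separable fingerprint/label sets for the BBB classifier,
  with the generating hyperplane returned for recovery tests;
* a compound table mapping planted names to a fixed panel of real
  drug-like structures, with BBB training labels from the standard
  TPSA <= 90 A^2 CNS-permeation heuristic, so end-to-end suitability is
  an independently computable oracle.

All generators are pure functions of their spec: the same seed yields
byte-identical outputs.  Background vocabulary is disjoint from the
question's content words by construction, and compound names are opaque
tokens (``cmpd_07``) so true/false retrieval labels are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, QABenchmarkItem, build_document
from .dcn import RelevancePair
from .embedding import EncoderConfig, embed_sentence
from .triage import CompoundRecord, fingerprint, parse_smiles, tpsa

#: The canonical mining question driving all synthetic fixtures.
QUESTION = "what are the drugs that affect oxidative stress in chronic diseases?"

#: Content words of the question (stopwords removed), the tokens planted
#: sentences may share with it.
QUESTION_CONTENT_WORDS = ("oxidative", "stress", "chronic", "diseases", "drugs", "affect")


class SyntheticError(Exception):
    pass


@dataclass(frozen=True)
class CorpusSpec:
    n_docs: int = 20
    n_compounds: int = 20
    filler_sentences_per_doc: int = 9
    plant_probability: float = 1.0
    background_vocab: int = 200
    overlap_tokens: int = 4
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0.0 <= self.plant_probability <= 1.0):
            raise SyntheticError("plant_probability must be in [0, 1]")
        if self.overlap_tokens < 1:
            raise SyntheticError("overlap_tokens must be >= 1")
        if not (1 <= self.overlap_tokens <= len(QUESTION_CONTENT_WORDS)):
            raise SyntheticError(
                f"overlap_tokens must be <= {len(QUESTION_CONTENT_WORDS)}"
            )


@dataclass(frozen=True)
class BBBSpec:
    """Recovery fixture for the BBB classifier.

    ``n_bits`` defaults to 32 so the linear rule is overdetermined
    (sample-to-dimension ratio ~10 at the default ``n_samples``), which a
    parameter-recovery test requires; it is independent of the 1024-bit
    chemistry fingerprints used on real molecules.
    """

    n_samples: int = 400
    n_bits: int = 32
    bit_density: float = 0.1
    flip_rate: float = 0.05
    seed: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.flip_rate < 0.5):
            raise SyntheticError("flip_rate must be in [0, 0.5)")
        if not (0.0 < self.bit_density < 1.0):
            raise SyntheticError("bit_density must be in (0, 1)")


# ---------------------------------------------------------------------------
# Corpus with planted answers
# ---------------------------------------------------------------------------


def _filler_sentence(rng: np.random.Generator, vocab: list[str]) -> str:
    words = rng.choice(vocab, size=8, replace=False)
    return " ".join(words.tolist()) + "."


def _planted_sentence(name: str, overlap_tokens: int) -> str:
    words = QUESTION_CONTENT_WORDS[:overlap_tokens]
    return f"Compound {name} attenuates {' '.join(words)} in patients."


def make_corpus(spec: CorpusSpec) -> tuple[Corpus, list[QABenchmarkItem]]:
    """Generate a corpus of filler documents with planted answers.

    With probability ``plant_probability`` a document carries one planted
    sentence naming a synthetic compound and sharing ``overlap_tokens``
    content words with the question; the gold list records the planted
    name (or nothing) per document.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = [f"tok{idx:04d}" for idx in range(spec.background_vocab)]
    compounds = [f"cmpd_{idx:02d}" for idx in range(spec.n_compounds)]
    documents = []
    gold: list[QABenchmarkItem] = []
    for d in range(spec.n_docs):
        doc_id = f"doc_{d:03d}"
        sentences = [
            _filler_sentence(rng, vocab) for _ in range(spec.filler_sentences_per_doc)
        ]
        planted: frozenset[str] = frozenset()
        if rng.random() < spec.plant_probability:
            name = compounds[d % spec.n_compounds]
            pos = int(rng.integers(0, len(sentences) + 1))
            sentences.insert(pos, _planted_sentence(name, spec.overlap_tokens))
            planted = frozenset({name})
        raw_text = " ".join(sentences)
        documents.append(build_document(doc_id, source="synthetic", raw_text=raw_text))
        gold.append(
            QABenchmarkItem(question=QUESTION, doc_id=doc_id, gold_compounds=planted)
        )
    corpus = Corpus(
        documents=documents,
        metadata={
            "generator": "litmine.synthetic.make_corpus",
            "prng": "numpy.random.default_rng(PCG64)",
            "spec": {
                "n_docs": spec.n_docs,
                "n_compounds": spec.n_compounds,
                "filler_sentences_per_doc": spec.filler_sentences_per_doc,
                "plant_probability": spec.plant_probability,
                "background_vocab": spec.background_vocab,
                "overlap_tokens": spec.overlap_tokens,
                "seed": spec.seed,
            },
        },
    )
    corpus.validate()
    return corpus, gold


# ---------------------------------------------------------------------------
# Relevance pairs
# ---------------------------------------------------------------------------


def make_relevance_pairs(
    corpus: Corpus,
    gold: list[QABenchmarkItem],
    n_irrelevant_per_doc: int = 1,
    encoder_config: EncoderConfig | None = None,
    seed: int = 0,
) -> list[RelevancePair]:
    """Embed (question, planted) pairs as label 1 and (question, random
    filler) pairs as label 0; balanced when ``n_irrelevant_per_doc`` is 1."""
    config = encoder_config or EncoderConfig()
    rng = np.random.default_rng(seed)
    by_doc = {d.doc_id: d for d in corpus.documents}
    q_emb = embed_sentence(QUESTION, config)
    pairs: list[RelevancePair] = []
    n_planted = 0
    for item in gold:
        doc = by_doc[item.doc_id]
        if not item.gold_compounds:
            continue
        planted = [
            s
            for s in doc.sentences
            if any(name in s.text for name in item.gold_compounds)
        ]
        fillers = [s for s in doc.sentences if s not in planted]
        for s in planted:
            pairs.append(
                RelevancePair(
                    question_embedding=q_emb,
                    answer_embedding=embed_sentence(s.text, config),
                    label=1,
                )
            )
            n_planted += 1
        if fillers:
            take = rng.choice(
                len(fillers), size=min(n_irrelevant_per_doc, len(fillers)), replace=False
            )
            for i in take:
                pairs.append(
                    RelevancePair(
                        question_embedding=q_emb,
                        answer_embedding=embed_sentence(fillers[int(i)].text, config),
                        label=0,
                    )
                )
    if n_planted == 0:
        raise SyntheticError("corpus contains no planted sentences")
    return pairs


# ---------------------------------------------------------------------------
# BBB fingerprint dataset
# ---------------------------------------------------------------------------


def make_bbb_dataset(spec: BBBSpec) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, float]]:
    """Noisy linearly separable bit vectors.

    A hyperplane is sampled from a seeded standard normal, bits are
    Bernoulli(bit_density), labels are the sign of the margin and are
    flipped independently at ``flip_rate``.  The generating (weights,
    bias) are returned so recovery can be tested against ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    w = rng.standard_normal(spec.n_bits)
    # Center the decision boundary at the expected active-bit mass so the
    # two classes are roughly balanced.
    b = -spec.bit_density * float(w.sum())
    X = (rng.random((spec.n_samples, spec.n_bits)) < spec.bit_density).astype(float)
    margins = X @ w + b
    y = np.where(margins >= 0.0, 1, -1)
    flips = rng.random(spec.n_samples) < spec.flip_rate
    y = np.where(flips, -y, y)
    return X, y, (w, b)


# ---------------------------------------------------------------------------
# Compound table for end-to-end fixtures
# ---------------------------------------------------------------------------

#: Fixed panel of real drug-like structures the synthetic compound names
#: map onto.  Mixed on purpose: low-TPSA CNS-permeant molecules and
#: high-TPSA non-permeant ones, so the fixture BBB classifier has both
#: classes and triage exercises every gate.
STRUCTURE_PANEL: tuple[tuple[str, str], ...] = (
    ("zileuton-like", "CC(c1cc2ccccc2s1)N(O)C(N)=O"),
    ("caffeic-acid-like", "Oc1ccc(/C=C/C(=O)O)cc1O"),
    ("ibuprofen-like", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    ("caffeine-like", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("acetaminophen-like", "CC(=O)Nc1ccc(O)cc1"),
    ("nicotine-like", "CN1CCC[C@H]1c1cccnc1"),
    ("melatonin-like", "CC(=O)NCCc1c[nH]c2ccc(OC)cc12"),
    ("sulforaphane-like", "CS(=O)CCCCN=C=S"),
    ("naproxen-like", "COc1ccc2cc(ccc2c1)C(C)C(=O)O"),
    ("aspirin-like", "CC(=O)Oc1ccccc1C(=O)O"),
    ("lisinopril-like", "NCCCC[C@H](N[C@@H](CCc1ccccc1)C(=O)O)C(=O)N1CCC[C@H]1C(=O)O"),
    ("methotrexate-like", "CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(cc1)C(=O)N[C@@H](CCC(=O)O)C(=O)O"),
    ("glucose-like", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
    ("ascorbate-like", "OC[C@H](O)[C@H]1OC(=O)C(O)=C1O"),
)

#: TPSA bound (Angstrom^2) of the standard CNS passive-permeation
#: heuristic used to label the fixture panel.
BBB_TPSA_BOUND = 90.0


def bbb_heuristic_label(smiles: str) -> int:
    """+1 (crosses) when TPSA <= 90 A^2, else -1."""
    return 1 if tpsa(parse_smiles(smiles)) <= BBB_TPSA_BOUND else -1


def make_compound_table(names: list[str]) -> list[CompoundRecord]:
    """Map synthetic compound names onto the structure panel (cycled in
    sorted-name order, so the mapping is independent of call order)."""
    return [
        CompoundRecord(name=name, smiles=STRUCTURE_PANEL[i % len(STRUCTURE_PANEL)][1])
        for i, name in enumerate(sorted(set(names)))
    ]


def make_panel_bbb_training_set(
    n_bits: int = 1024, radius: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Fingerprints and heuristic labels for the full structure panel."""
    X = np.stack(
        [fingerprint(parse_smiles(smi), n_bits=n_bits, radius=radius) for _, smi in STRUCTURE_PANEL]
    )
    y = np.array([bbb_heuristic_label(smi) for _, smi in STRUCTURE_PANEL])
    return X, y
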