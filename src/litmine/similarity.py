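"""Question–sentence similarity scoring, per-document answer assignment,
and retrieval evaluation.

Two similarity methods are supported:

* ``inner_product`` — dot product of the (normalized) sentence embeddings;
  on unit vectors this is cosine similarity in [-1, 1].
* ``directed_hausdorff`` — the directed Hausdorff distance between the
  question's and the sentence's token-embedding point sets, used as a
  tractable stand-in for the Gromov–Hausdorff distance (which requires
  solving an NP-hard correspondence problem).  Distances are negated so
  that "higher is better" holds for both methods.

Each document contributes exactly one answer: the sentence with the
highest score, ties broken by smallest sentence id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .corpus import Document, QABenchmarkItem, Sentence
from .embedding import EncoderConfig, TokenEmbeddingMatrix, embed_sentence, embed_tokens

METHODS = ("inner_product", "directed_hausdorff")


class SimilarityError(Exception):
    pass


@dataclass(frozen=True)
class RankedAnswer:
    """The winning sentence of one document under one method."""

    doc_id: str
    sentence: Sentence
    method: str
    score: float
    rank_within_document: int = 1


def inner_product_score(q: np.ndarray, s: np.ndarray) -> float:
    q = np.asarray(q, dtype=float)
    s = np.asarray(s, dtype=float)
    if q.shape != s.shape:
        raise SimilarityError(f"dimension mismatch: {q.shape} vs {s.shape}")
    return float(q @ s)


def directed_hausdorff_distance(
    A: TokenEmbeddingMatrix | np.ndarray, B: TokenEmbeddingMatrix | np.ndarray
) -> float:
    """max over points a in A of the distance from a to its nearest point in B.

    Asymmetric: h(A, B) = 0 whenever every point of A coincides with some
    point of B, regardless of how much of B is uncovered.
    """
    a = A.rows if isinstance(A, TokenEmbeddingMatrix) else np.asarray(A, dtype=float)
    b = B.rows if isinstance(B, TokenEmbeddingMatrix) else np.asarray(B, dtype=float)
    if a.size == 0 or b.size == 0:
        raise SimilarityError("empty point set")
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[1] != b.shape[1]:
        raise SimilarityError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    return float(cdist(a, b).min(axis=1).max())


def score_sentence(
    question: str, sentence_text: str, method: str, config: EncoderConfig
) -> float:
    """Similarity of one sentence to the question; higher = more similar."""
    if method == "inner_product":
        return inner_product_score(
            embed_sentence(question, config), embed_sentence(sentence_text, config)
        )
    if method == "directed_hausdorff":
        return -directed_hausdorff_distance(
            embed_tokens(question, config), embed_tokens(sentence_text, config)
        )
    raise SimilarityError(f"unknown method {method!r}; expected one of {METHODS}")


def answer_for_document(
    question: str, document: Document, method: str, config: EncoderConfig
) -> RankedAnswer:
    """Score every sentence and return the argmax (ties -> smallest sent_id)."""
    if not document.sentences:
        raise SimilarityError(f"document {document.doc_id} has no sentences")
    scores = [score_sentence(question, s.text, method, config) for s in document.sentences]
    best = int(np.argmax(scores))  # argmax returns the first maximum
    return RankedAnswer(
        doc_id=document.doc_id,
        sentence=document.sentences[best],
        method=method,
        score=scores[best],
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fscore(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def evaluate(
    predictions: Sequence[RankedAnswer | None],
    gold: Sequence[QABenchmarkItem],
) -> BenchmarkCounts:
    """Confusion counts of per-document answers against gold compounds.

    ``predictions`` aligns with ``gold`` by doc_id; ``None`` marks an
    abstention.  A returned sentence is a true positive when it contains
    any gold compound name as a case-insensitive substring; answering a
    document with no gold answer counts as a false positive, abstaining
    on it as a true negative.
    """
    by_doc: dict[str, RankedAnswer | None] = {}
    gold_ids = {g.doc_id for g in gold}
    for p in predictions:
        if p is None:
            continue
        if p.doc_id not in gold_ids:
            raise SimilarityError(f"prediction for unknown doc_id {p.doc_id!r}")
        by_doc[p.doc_id] = p

    tp = fp = tn = fn = 0
    for item in gold:
        pred = by_doc.get(item.doc_id)
        has_answer = bool(item.gold_compounds)
        if pred is None:
            if has_answer:
                fn += 1
            else:
                tn += 1
        else:
            text = pred.sentence.text.lower()
            hit = any(name.lower() in text for name in item.gold_compounds)
            if hit:
                tp += 1
            else:
                fp += 1
    return BenchmarkCounts(tp=tp, fp=fp, tn=tn, fn=fn)
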