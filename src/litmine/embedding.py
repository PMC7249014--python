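"""Sentence embeddings: a deterministic hashed n-gram encoder plus an
adapter contract for pretrained deep-averaging-network (DAN) encoders.

The default encoder mirrors the shape of a DAN sentence encoder — per-unit
(word and bigram) vectors are averaged into a fixed-dimension sentence
vector — but replaces learned word embeddings with signed feature hashing
and the learned feedforward stage with the identity.  This keeps the whole
retrieval pipeline deterministic, dependency-free, and testable, while a
real pretrained encoder (e.g. a 512-dim universal sentence encoder) can be
plugged in through :func:`register_external_encoder` without touching any
downstream code.

Hashing is 64-bit FNV-1a over UTF-8 bytes, salted by ``hash_seed``:
the unit's index is ``hash % dimension`` and its sign comes from bit 63.
FNV-1a is fully specified, so embeddings are bitwise reproducible across
platforms and Python builds (unlike the builtin ``hash``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class EmbeddingError(Exception):
    pass


@dataclass(frozen=True)
class EncoderConfig:
    """Configuration of the default hashing encoder.

    dimension : embedding length (512 matches common pretrained sentence
        encoders so the external adapter is drop-in compatible).
    ngram_orders : which n-gram orders contribute unit vectors; {1, 2}
        averages words and adjacent bigrams.
    hash_seed : salt for the portable hash; changing it permutes the
        index/sign pattern.
    normalize : L2-normalize the sentence vector (makes the inner product
        a cosine similarity).
    """

    kind: str = "hashing_dan"
    dimension: int = 512
    ngram_orders: frozenset[int] = frozenset({1, 2})
    hash_seed: int = 0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise EmbeddingError("dimension must be >= 2")
        if not set(self.ngram_orders) <= {1, 2, 3}:
            raise EmbeddingError("ngram_orders must be a subset of {1, 2, 3}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "dimension": self.dimension,
            "ngram_orders": sorted(self.ngram_orders),
            "hash_seed": self.hash_seed,
            "normalize": self.normalize,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        d = dict(d)
        if "ngram_orders" in d:
            d["ngram_orders"] = frozenset(d["ngram_orders"])
        return cls(**d)


@dataclass(frozen=True)
class TokenEmbeddingMatrix:
    """Per-unit embedding rows (words first, then bigrams, in text order)."""

    rows: np.ndarray  # (n_units, dimension)
    token_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.rows.ndim != 2 or self.rows.shape[0] != len(self.token_labels):
            raise EmbeddingError("rows/labels shape mismatch")


def fnv1a64(data: str, seed: int = 0) -> int:
    """Portable 64-bit FNV-1a hash of a UTF-8 string, salted by ``seed``."""
    h = _FNV_OFFSET
    for b in seed.to_bytes(8, "little", signed=False) + data.encode("utf-8"):
        h ^= b
        h = (h * _FNV_PRIME) & _MASK64
    return h


def tokenize_for_embedding(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric runs."""
    return _TOKEN_RE.findall(text.lower())


def _units(tokens: Sequence[str], orders: frozenset[int]) -> list[str]:
    units: list[str] = []
    for n in sorted(orders):
        units.extend(" ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1))
    return units


def embed_tokens(sentence_text: str, config: EncoderConfig) -> TokenEmbeddingMatrix:
    """One signed-unit-basis row per word/bigram unit.

    Each unit hashes to a single index in [0, dimension) and a sign in
    {-1, +1}; its row is that signed standard basis vector.
    """
    tokens = tokenize_for_embedding(sentence_text)
    if not tokens:
        raise EmbeddingError("empty sentence")
    units = _units(tokens, config.ngram_orders)
    rows = np.zeros((len(units), config.dimension))
    for i, unit in enumerate(units):
        h = fnv1a64(unit, config.hash_seed)
        sign = -1.0 if (h >> 63) & 1 else 1.0
        rows[i, h % config.dimension] = sign
    return TokenEmbeddingMatrix(rows=rows, token_labels=tuple(units))


def embed_sentence(sentence_text: str, config: EncoderConfig) -> np.ndarray:
    """Mean of the unit rows, optionally L2-normalized."""
    matrix = embed_tokens(sentence_text, config)
    vec = matrix.rows.mean(axis=0)
    if config.normalize:
        norm = np.linalg.norm(vec)
        if norm == 0.0:  # cancellation is possible but astronomically unlikely
            raise EmbeddingError("degenerate zero embedding")
        vec = vec / norm
    return vec


# ---------------------------------------------------------------------------
# External encoder adapter
# ---------------------------------------------------------------------------


@dataclass
class ExternalEncoder:
    """Handle wrapping a pretrained sentence encoder callable."""

    fn: Callable[[str], Sequence[float]]
    dimension: int
    name: str = "external"

    def __call__(self, sentence_text: str) -> np.ndarray:
        vec = np.asarray(self.fn(sentence_text), dtype=float)
        if vec.shape != (self.dimension,):
            raise EmbeddingError(
                f"adapter {self.name!r} returned shape {vec.shape}, "
                f"declared dimension {self.dimension}"
            )
        return vec


def register_external_encoder(
    fn: Callable[[str], Sequence[float]],
    dimension: int,
    name: str = "external",
    probe: str = "the quick brown fox",
) -> ExternalEncoder:
    """Validate and wrap an external encoder callable.

    Registration embeds a probe sentence twice: the dimension must match
    the declaration and the two outputs must be identical (pretrained
    encoders are deterministic per version; a stochastic adapter would
    silently corrupt ranking).
    """
    handle = ExternalEncoder(fn=fn, dimension=dimension, name=name)
    first = handle(probe)
    second = handle(probe)
    if not np.array_equal(first, second):
        raise EmbeddingError(f"adapter {name!r} is non-deterministic")
    return handle
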