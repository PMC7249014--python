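"""Document ingestion, sentence tokenization, and corpus persistence.

A corpus is a set of documents, each split into unique sentences with
character-offset provenance so every downstream answer can be traced back
to the exact span of source text it came from. Persistence is plain JSON
with an explicit schema version; loading a file written by a different
schema fails loudly rather than coercing silently.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

SCHEMA_VERSION = 1

#: Minimum sentence length in characters; shorter fragments (stray
#: punctuation, page numbers) are discarded.
MIN_SENTENCE_LEN = 3

#: Tokens that end with a period but do not terminate a sentence.
ABBREVIATIONS = frozenset(
    {
        "e.g", "i.e", "etc", "cf", "vs", "al", "fig", "figs", "eq", "no",
        "dr", "mr", "mrs", "ms", "prof", "st", "approx", "ca",
    }
)


class CorpusError(Exception):
    """Raised for unreadable, malformed, or version-mismatched corpus data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sentence:
    """One tokenized sentence with provenance offsets.

    ``start``/``end`` are 0-based half-open character offsets into the
    parent document's raw text, so ``raw_text[start:end] == text``.
    """

    sent_id: int
    doc_id: str
    text: str
    start: int
    end: int

    def validate(self, raw_text: str) -> None:
        if not (0 <= self.start < self.end <= len(raw_text)):
            raise CorpusError(
                f"sentence {self.doc_id}/{self.sent_id}: offsets "
                f"[{self.start}, {self.end}) out of range"
            )
        if raw_text[self.start : self.end] != self.text:
            raise CorpusError(
                f"sentence {self.doc_id}/{self.sent_id}: text does not match span"
            )


@dataclass
class Document:
    doc_id: str
    source: str
    raw_text: str
    sentences: list[Sentence] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        prev_start = -1
        for s in self.sentences:
            s.validate(self.raw_text)
            if s.start <= prev_start:
                raise CorpusError(f"document {self.doc_id}: sentences out of order")
            prev_start = s.start
            if s.text in seen:
                raise CorpusError(f"document {self.doc_id}: duplicate sentence text")
            seen.add(s.text)


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise CorpusError("duplicate doc_id in corpus")
        for d in self.documents:
            d.validate()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.documents == other.documents and self.metadata == other.metadata


@dataclass(frozen=True)
class QABenchmarkItem:
    """A gold item: any returned sentence containing one of
    ``gold_compounds`` (case-insensitive substring) counts as correct.
    An empty ``gold_compounds`` marks a document with no answer."""

    question: str
    doc_id: str
    gold_compounds: frozenset[str]


# ---------------------------------------------------------------------------
# Text extraction
# ---------------------------------------------------------------------------

#: Optional registry of PDF extraction backends.  A backend is a callable
#: ``path -> str``.  None is bundled; pdfminer.six or Tika can be plugged in.
_PDF_BACKEND: Callable[[str], str] | None = None


def register_pdf_backend(backend: Callable[[str], str]) -> None:
    global _PDF_BACKEND
    _PDF_BACKEND = backend


def extract_text(path: str | Path, format: str = "plain") -> str:
    """Extract raw text from a document file.

    ``format`` is ``plain`` or ``pdf``; PDF extraction is delegated to a
    backend registered via :func:`register_pdf_backend`.
    """
    path = Path(path)
    if format == "plain":
        try:
            text = path.read_text(encoding="utf-8")
        except OSError as exc:
            raise CorpusError(f"unreadable file {path}: {exc}") from exc
    elif format == "pdf":
        if _PDF_BACKEND is None:
            raise CorpusError("no pdf backend configured")
        text = _PDF_BACKEND(str(path))
    else:
        raise CorpusError(f"unsupported format {format!r}")
    if not text or not text.strip():
        raise CorpusError(f"empty extraction result for {path}")
    return text


# ---------------------------------------------------------------------------
# Sentence tokenization
# ---------------------------------------------------------------------------

_BOUNDARY = re.compile(r"[.?!]+(?=\s)|[.?!]+$")
_LAST_WORD = re.compile(r"([A-Za-z][A-Za-z.]*)$")


def _default_splitter(raw_text: str) -> list[tuple[int, int]]:
    """Yield (start, end) spans of candidate sentences.

    Splits after runs of terminal punctuation followed by whitespace,
    unless the token before the period is a known abbreviation or a
    single letter (initials).
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY.finditer(raw_text):
        end = m.end()
        before = raw_text[start : m.start()]
        word = _LAST_WORD.search(before)
        if word and m.group().startswith("."):
            token = word.group(1).rstrip(".").lower()
            if token in ABBREVIATIONS or len(token) == 1:
                continue
        spans.append((start, end))
        start = end
    if start < len(raw_text):
        spans.append((start, len(raw_text)))
    return spans


def tokenize_sentences(
    raw_text: str,
    doc_id: str = "",
    splitter: Callable[[str], list[tuple[int, int]]] | None = None,
    min_len: int = MIN_SENTENCE_LEN,
) -> list[Sentence]:
    """Split raw text into unique sentences with offsets.

    Duplicate sentences (exact text match after trimming) are removed,
    keeping the first occurrence; fragments shorter than ``min_len``
    characters are dropped.
    """
    if not raw_text:
        return []
    splitter = splitter or _default_splitter
    sentences: list[Sentence] = []
    seen: set[str] = set()
    sent_id = 0
    for span_start, span_end in splitter(raw_text):
        chunk = raw_text[span_start:span_end]
        stripped = chunk.strip()
        if len(stripped) < min_len or stripped in seen:
            continue
        seen.add(stripped)
        start = span_start + (len(chunk) - len(chunk.lstrip()))
        end = start + len(stripped)
        sentences.append(
            Sentence(sent_id=sent_id, doc_id=doc_id, text=stripped, start=start, end=end)
        )
        sent_id += 1
    return sentences


def build_document(doc_id: str, source: str, raw_text: str, **kw) -> Document:
    doc = Document(
        doc_id=doc_id,
        source=source,
        raw_text=raw_text,
        sentences=tokenize_sentences(raw_text, doc_id=doc_id, **kw),
    )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    corpus.validate()
    payload = {
        "schema_version": SCHEMA_VERSION,
        "metadata": corpus.metadata,
        "documents": [
            {
                "doc_id": d.doc_id,
                "source": d.source,
                "raw_text": d.raw_text,
                "sentences": [
                    {"sent_id": s.sent_id, "text": s.text, "start": s.start, "end": s.end}
                    for s in d.sentences
                ],
            }
            for d in corpus.documents
        ],
    }
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True, ensure_ascii=False), encoding="utf-8"
    )


def load_corpus(path: str | Path) -> Corpus:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise CorpusError(f"malformed corpus file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise CorpusError(
            f"corpus schema version mismatch: file has {version!r}, "
            f"this build reads {SCHEMA_VERSION}"
        )
    try:
        documents = [
            Document(
                doc_id=d["doc_id"],
                source=d["source"],
                raw_text=d["raw_text"],
                sentences=[
                    Sentence(
                        sent_id=s["sent_id"],
                        doc_id=d["doc_id"],
                        text=s["text"],
                        start=s["start"],
                        end=s["end"],
                    )
                    for s in d["sentences"]
                ],
            )
            for d in payload["documents"]
        ]
        corpus = Corpus(documents=documents, metadata=payload["metadata"])
    except (KeyError, TypeError) as exc:
        raise CorpusError(f"malformed corpus file {path}: missing field {exc}") from exc
    corpus.validate()
    return corpus


def save_benchmark(items: Sequence[QABenchmarkItem], path: str | Path) -> None:
    payload = [
        {
            "question": it.question,
            "doc_id": it.doc_id,
            "gold_compounds": sorted(it.gold_compounds),
        }
        for it in items
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


def load_benchmark(path: str | Path) -> list[QABenchmarkItem]:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return [
            QABenchmarkItem(
                question=it["question"],
                doc_id=it["doc_id"],
                gold_compounds=frozenset(it["gold_compounds"]),
            )
            for it in payload
        ]
    except (OSError, json.JSONDecodeError, KeyError, TypeError) as exc:
        raise CorpusError(f"malformed benchmark file {path}: {exc}") from exc
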