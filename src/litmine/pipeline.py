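"""End-to-end orchestration: mine -> relevance filter -> compound triage.

The pipeline answers one question against a corpus (one top sentence per
document), keeps the answers whose differential-convolution relevance to
the question reaches the acceptance threshold, matches compound names
from a provided dictionary against the retained sentences, triages the
matched compounds, and emits a ranked candidate report in which every row
is traceable back to its source sentence (doc_id, sent_id, offsets are in
the corpus).

Errors are classified so the command-line layer can map them onto stable
exit codes: configuration problems, missing/invalid data, and model
problems are distinct failure modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .corpus import Corpus, load_corpus
from .dcn import DCNConfig, DCNModel, load_model, relevance_score
from .embedding import EncoderConfig, embed_sentence
from .similarity import RankedAnswer, answer_for_document
from .triage import (
    BBBModel,
    CompoundRecord,
    LipinskiRuleConfig,
    TriageVerdict,
    load_bbb_model,
    triage,
)

logger = logging.getLogger(__name__)


class PipelineConfigError(Exception):
    """Invalid or inconsistent configuration."""


class PipelineDataError(Exception):
    """Missing or malformed input data."""


class PipelineModelError(Exception):
    """Missing or malformed trained model."""


REPORT_COLUMNS = [
    "compound",
    "doc_id",
    "sent_id",
    "answer_sentence",
    "similarity",
    "relevance",
    "mw",
    "hbd",
    "hba",
    "tpsa",
    "rotb",
    "clogp",
    "violations",
    "poor_oral",
    "clogp_band",
    "bbb_score",
    "bbb_crossing",
    "suitable",
    "rank",
]


@dataclass
class PipelineConfig:
    question: str
    corpus_path: str
    compound_table_path: str
    dcn_model_path: str
    bbb_model_path: str | None = None
    method: str = "inner_product"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    threshold: float | None = None  # None -> the DCN config's threshold
    lipinski: LipinskiRuleConfig = field(default_factory=LipinskiRuleConfig)
    out_tsv: str = "report.tsv"
    out_json: str = "report.json"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        except (OSError, yaml.YAMLError) as exc:
            raise PipelineConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise PipelineConfigError(f"config {path} is not a mapping")
        try:
            encoder = EncoderConfig.from_dict(raw.pop("encoder", {}))
            lipinski = LipinskiRuleConfig(**raw.pop("lipinski", {}))
            return cls(encoder=encoder, lipinski=lipinski, **raw)
        except Exception as exc:
            raise PipelineConfigError(f"invalid config {path}: {exc}") from exc


def load_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a name,smiles CSV/TSV table (delimiter sniffed from suffix)."""
    path = Path(path)
    if not path.exists():
        raise PipelineDataError(f"compound table not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
        df.columns = [c.strip().lower() for c in df.columns]
        return [
            CompoundRecord(name=str(r["name"]), smiles=str(r["smiles"]))
            for _, r in df.iterrows()
        ]
    except (KeyError, ValueError, pd.errors.ParserError) as exc:
        raise PipelineDataError(f"malformed compound table {path}: {exc}") from exc


def match_compounds(
    sentence_text: str, compounds: Sequence[CompoundRecord]
) -> list[CompoundRecord]:
    """Dictionary matching: compound names appearing in the sentence
    (case-insensitive substring)."""
    text = sentence_text.lower()
    return [c for c in compounds if c.name.lower() in text]


@dataclass
class PipelineResult:
    answers: list[RankedAnswer]
    retained: list[tuple[RankedAnswer, float]]  # (answer, relevance)
    verdicts: list[TriageVerdict]
    report: pd.DataFrame


def run_pipeline_objects(
    question: str,
    corpus: Corpus,
    compounds: Sequence[CompoundRecord],
    dcn_model: DCNModel,
    bbb_model: BBBModel | None,
    encoder: EncoderConfig | None = None,
    method: str = "inner_product",
    threshold: float | None = None,
    lipinski: LipinskiRuleConfig | None = None,
) -> PipelineResult:
    """Run mine -> filter -> triage on in-memory objects."""
    encoder = encoder or EncoderConfig()
    lipinski = lipinski or LipinskiRuleConfig()
    if threshold is None:
        threshold = dcn_model.config.threshold
    if dcn_model.config.input_dim != encoder.dimension:
        raise PipelineConfigError(
            f"DCN input_dim {dcn_model.config.input_dim} != encoder dimension "
            f"{encoder.dimension}"
        )
    if not corpus.documents:
        raise PipelineDataError("corpus has no documents")

    # Stage 1: mine one answer per document.
    answers = [answer_for_document(question, d, method, encoder) for d in corpus.documents]
    logger.info("mine: %d documents -> %d answers", len(corpus.documents), len(answers))

    # Stage 2: relevance filter at the acceptance threshold.
    q_emb = embed_sentence(question, encoder)
    retained: list[tuple[RankedAnswer, float]] = []
    for ans in answers:
        rel = relevance_score(q_emb, embed_sentence(ans.sentence.text, encoder), dcn_model)
        if rel >= threshold:
            retained.append((ans, rel))
    logger.info(
        "filter: %d answers -> %d retained at threshold %.3f",
        len(answers),
        len(retained),
        threshold,
    )
    if not retained:
        logger.warning("relevance filter removed every answer")

    # Stage 3: dictionary-match compounds in retained sentences.
    hits: dict[str, tuple[RankedAnswer, float]] = {}
    for ans, rel in retained:
        for comp in match_compounds(ans.sentence.text, compounds):
            hits.setdefault(comp.name, (ans, rel))
    logger.info("match: %d retained sentences -> %d compounds", len(retained), len(hits))

    # Stage 4: triage the matched compounds.
    matched_records = [c for c in compounds if c.name in hits]
    verdicts = triage(matched_records, rule_config=lipinski, bbb_model=bbb_model)
    logger.info(
        "triage: %d compounds -> %d suitable",
        len(verdicts),
        sum(v.suitable for v in verdicts),
    )

    rows = []
    for v in verdicts:
        ans, rel = hits[v.name]
        rows.append(
            {
                "compound": v.name,
                "doc_id": ans.doc_id,
                "sent_id": ans.sentence.sent_id,
                "answer_sentence": ans.sentence.text,
                "similarity": ans.score,
                "relevance": rel,
                "mw": v.descriptors.mw,
                "hbd": v.descriptors.hbd,
                "hba": v.descriptors.hba,
                "tpsa": v.descriptors.tpsa,
                "rotb": v.descriptors.rotatable_bonds,
                "clogp": v.descriptors.clogp,
                "violations": v.violations,
                "poor_oral": v.poor_oral,
                "clogp_band": v.clogp_band,
                "bbb_score": v.bbb_score,
                "bbb_crossing": v.bbb_crossing,
                "suitable": v.suitable,
                "rank": v.rank,
            }
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return PipelineResult(answers=answers, retained=retained, verdicts=verdicts, report=report)


def write_report(report: pd.DataFrame, tsv_path: str | Path, json_path: str | Path) -> None:
    """Twin TSV + JSON outputs, stable field order, fixed float format."""
    report.to_csv(tsv_path, sep="\t", index=False, float_format="%.6f")
    Path(json_path).write_text(
        report.to_json(orient="records", indent=1, double_precision=6) + "\n",
        encoding="utf-8",
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline from a configuration object with file IO."""
    if not Path(config.corpus_path).exists():
        raise PipelineDataError(f"corpus not found: {config.corpus_path}")
    corpus = load_corpus(config.corpus_path)
    compounds = load_compound_table(config.compound_table_path)
    if not Path(config.dcn_model_path).exists():
        raise PipelineModelError(f"DCN model not found: {config.dcn_model_path}")
    try:
        dcn_model = load_model(config.dcn_model_path)
    except Exception as exc:
        raise PipelineModelError(str(exc)) from exc
    bbb_model = None
    if config.bbb_model_path is not None:
        if not Path(config.bbb_model_path).exists():
            raise PipelineModelError(f"BBB model not found: {config.bbb_model_path}")
        try:
            bbb_model = load_bbb_model(config.bbb_model_path)
        except Exception as exc:
            raise PipelineModelError(str(exc)) from exc
    result = run_pipeline_objects(
        question=config.question,
        corpus=corpus,
        compounds=compounds,
        dcn_model=dcn_model,
        bbb_model=bbb_model,
        encoder=config.encoder,
        method=config.method,
        threshold=config.threshold,
        lipinski=config.lipinski,
    )
    write_report(result.report, config.out_tsv, config.out_json)
    return result
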