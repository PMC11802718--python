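"""Pipeline configuration, JSONL I/O and the end-to-end run.

All record files are JSON Lines: one object per line, so free clinical text
with embedded delimiters and newlines round-trips safely.  Every output
file starts with a header object (``"__header__": true``) embedding the
run's configuration and its hash for provenance; readers skip header lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from pydantic import BaseModel

from .backends import HallucinatingBackend, NoisyBackend, OracleBackend
from .embedding import EmbedderContract, HashingNgramEmbedder
from .evaluation import (
    EvalRecord,
    ScoreTable,
    candidate_count_report,
    macro_table,
    scenario_histogram,
    score_answer,
)
from .extraction import (
    ExtractionParams,
    GenerationBackend,
    GenerationConfig,
    run_extraction,
)
from .lexicon import CategoryLexicon, SUDCategory, lexicon_map
from .postprocess import FinalAnswer, postprocess_note

log = logging.getLogger(__name__)


class MalformedRecordError(ValueError):
    pass


class PipelineConfig(BaseModel):
    """Fully serialisable run configuration; hashed into output headers."""

    lexicon_path: str | None = None
    backend: str = "oracle"
    window: int | None = None  # None: planned from the prompt length
    stride: int = 128
    max_len: int = 512
    min_len: int = 5  # grounding filter common-substring length
    metric: Literal["euclidean", "cosine"] = "euclidean"
    dedup: bool = True
    multiset: bool = True
    hallucination_rate: float = 0.2
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_jsonl(path: str | Path) -> list[dict]:
    """Read a JSONL file, skipping header objects.

    A malformed line raises :class:`MalformedRecordError` naming the line
    number; an empty file yields an empty list.
    """
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise MalformedRecordError(f"{path}: malformed JSON on line {lineno}") from exc
            if isinstance(obj, dict) and obj.get("__header__"):
                continue
            records.append(obj)
    return records


def write_jsonl(
    path: str | Path, records: Iterable[Mapping], header: Mapping | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header is not None:
            fh.write(json.dumps({"__header__": True, **header}) + "\n")
        for rec in records:
            fh.write(json.dumps(dict(rec)) + "\n")


def answer_to_record(a: FinalAnswer) -> dict:
    return {
        "note_id": a.note_id,
        "category": a.category.value,
        "text": a.text,
        "selection_method": a.selection_method,
        "n_candidates": a.n_candidates,
        "n_survivors": a.n_survivors,
        "filtered": list(a.filtered),
    }


def make_backend(config: PipelineConfig, gold: Sequence[Mapping] | None) -> GenerationBackend:
    """Instantiate the configured backend (mock backends need gold spans)."""
    name = config.backend
    if name in {"oracle", "noisy", "hallucinating"}:
        if gold is None:
            raise ValueError(f"backend {name!r} requires gold annotations")
        if name == "oracle":
            return OracleBackend(gold)
        if name == "noisy":
            return NoisyBackend(gold)
        return HallucinatingBackend(gold, rate=config.hallucination_rate, seed=config.seed)
    if name.startswith("hf:"):
        from .backends import HFSeq2SeqBackend

        return HFSeq2SeqBackend(name.removeprefix("hf:"))
    raise ValueError(f"unknown backend {name!r}")


def run_pipeline(
    config: PipelineConfig,
    notes: Sequence[Mapping],
    gold: Sequence[Mapping] | None = None,
    backend: GenerationBackend | None = None,
    embedder: EmbedderContract | None = None,
    categories: Sequence[SUDCategory] | None = None,
) -> tuple[list[FinalAnswer], dict | None]:
    """Extract and post-process every (note, category) pair; score if gold given.

    Returns the final answers and, when gold annotations are supplied, a
    report dict with the macro score table, the per-category error-scenario
    histogram, and the candidate-count report (surviving distinct candidates
    per note versus note length).
    """
    lexicons = lexicon_map(config.lexicon_path)
    categories = list(categories) if categories else list(SUDCategory)
    backend = backend or make_backend(config, gold)
    embedder = embedder or HashingNgramEmbedder()
    params = ExtractionParams(stride=config.stride, max_len=config.max_len, window=config.window)
    cfg = GenerationConfig()

    gold_by_pair: dict[tuple[str, SUDCategory], str] = {}
    for rec in gold or ():
        gold_by_pair[(str(rec["note_id"]), SUDCategory(rec["category"]))] = rec["span_text"]

    answers: list[FinalAnswer] = []
    records: list[EvalRecord] = []
    counts: dict[tuple[str, SUDCategory], int] = {}
    lengths: dict[str, int] = {}
    stage_counts = {"notes": 0, "chunks": 0, "candidates": 0, "survivors": 0, "sentinels": 0}

    for note in notes:
        note_id = str(note["note_id"])
        lengths[note_id] = len(note["text"].split())
        stage_counts["notes"] += 1
        for category in categories:
            lex = lexicons[category]
            candidates = run_extraction(note, category, backend, cfg, params)
            final = postprocess_note(
                candidates,
                note["text"],
                lex,
                embedder,
                min_len=config.min_len,
                metric=config.metric,
                dedup=config.dedup,
            )
            answers.append(final)
            counts[(note_id, category)] = final.n_survivors
            stage_counts["candidates"] += len(candidates)
            stage_counts["survivors"] += final.n_survivors
            stage_counts["sentinels"] += int(final.text == "unanswerable")
            if category is categories[0]:
                stage_counts["chunks"] += len(candidates)
            if gold is not None:
                records.append(
                    score_answer(
                        note_id,
                        category,
                        gold_by_pair.get((note_id, category)),
                        final.text,
                        multiset=config.multiset,
                    )
                )
    log.info("pipeline stage counts: %s", stage_counts)

    report = None
    if gold is not None:
        report = {
            "scores": macro_table(records),
            "scenarios": scenario_histogram(records),
            "candidate_counts": candidate_count_report(lengths, counts),
            "records": records,
            "stage_counts": stage_counts,
        }
    return answers, report


def score_table_from_files(
    gold_path: str | Path, answers_path: str | Path, multiset: bool = True
) -> tuple[ScoreTable, list[EvalRecord]]:
    """Score an answers JSONL file against a gold JSONL file."""
    gold = read_jsonl(gold_path)
    answers = read_jsonl(answers_path)
    gold_by_pair = {
        (str(r["note_id"]), SUDCategory(r["category"])): r["span_text"] for r in gold
    }
    records = [
        score_answer(
            str(a["note_id"]),
            SUDCategory(a["category"]),
            gold_by_pair.get((str(a["note_id"]), SUDCategory(a["category"]))),
            a["text"],
            multiset=multiset,
        )
        for a in answers
    ]
    return macro_table(records), records
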