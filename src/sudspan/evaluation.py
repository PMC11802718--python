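"""Strict and relaxed span evaluation, macro tables, and candidate-count reports.

Two string-matching criteria score a predicted span against the gold span:

* **strict** -- binary exact match between normalised strings (casefolded,
  whitespace-collapsed, the unanswerable sentinel treated as the empty
  answer).  The case rules are: precision and recall both 1 gives F1 = 1;
  recall 1 with precision below 1 gives 0; recall 0 gives 0.  On a note
  with no target information, an empty answer (no false positives) scores
  1 and any generated tokens score 0.
* **relaxed** -- token-multiset overlap.  TP counts tokens common to gold
  and prediction, FN tokens only in gold, FP tokens only in the prediction;
  P = TP/(TP+FP), R = TP/(TP+FN), F1 their harmonic mean.  An empty gold
  and empty prediction scores (1, 1, 1).

The token unit is the whitespace token after lowercasing and isolating
punctuation, except that "/" is kept intra-token so clinical abbreviations
like "d/o" survive as single tokens.  Multiset (not set) counting makes
repeated words in verbose generations cost precision; a ``multiset=False``
switch collapses to sets.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import is_unanswerable
from .lexicon import SUDCategory

log = logging.getLogger(__name__)

Scenario = Literal["strict_match", "recall_only", "precision_only", "no_match", "other"]

_TOKEN_RE = re.compile(r"[a-z0-9/]+|[^\sa-z0-9/]")


def answer_tokens(text: str, multiset: bool = True) -> Counter:
    """Tokenise an answer for relaxed scoring.

    The sentinel (or an answer containing it) maps to the empty multiset.
    """
    if not text or is_unanswerable(text):
        return Counter()
    toks = _TOKEN_RE.findall(text.lower())
    return Counter(toks) if multiset else Counter(set(toks))


def relaxed_scores(gold: Counter, pred: Counter) -> tuple[float, float, float]:
    """Token-overlap precision, recall and F1 with the empty-side conventions.

    Both empty -> (1, 1, 1); only the prediction empty -> (1, 0, 0);
    only the gold empty -> (0, 1, 0).
    """
    tp = sum((gold & pred).values())
    fn = sum((gold - pred).values())
    fp = sum((pred - gold).values())
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f1


def _strict_norm(text: str) -> str:
    if is_unanswerable(text):
        return ""
    return " ".join(text.casefold().split())


def strict_f1(gold_text: str, pred_text: str) -> float:
    """1.0 iff the normalised prediction exactly equals the normalised gold.

    Both empty (a no-information note answered with the sentinel) counts as
    an exact match.
    """
    return 1.0 if _strict_norm(gold_text) == _strict_norm(pred_text) else 0.0


def classify_scenario(precision: float, recall: float) -> Scenario:
    """Five-way error scenario from the relaxed precision/recall, in order:
    (i) both 1, (ii) only recall 1, (iii) only precision 1, (iv) both 0,
    (v) anything else."""
    if precision == 1.0 and recall == 1.0:
        return "strict_match"
    if recall == 1.0:
        return "recall_only"
    if precision == 1.0:
        return "precision_only"
    if precision == 0.0 and recall == 0.0:
        return "no_match"
    return "other"


@dataclass(frozen=True)
class EvalRecord:
    note_id: str
    category: SUDCategory
    positive: bool  # the gold annotation marks this (note, category) positive
    relaxed_precision: float
    relaxed_recall: float
    relaxed_f1: float
    strict_f1: float
    scenario: Scenario


def score_answer(
    note_id: str,
    category: SUDCategory,
    gold_text: str | None,
    pred_text: str,
    multiset: bool = True,
) -> EvalRecord:
    """Score one predicted answer against the gold span (None = negative note)."""
    gold = gold_text or ""
    p, r, f1 = relaxed_scores(
        answer_tokens(gold, multiset), answer_tokens(pred_text, multiset)
    )
    return EvalRecord(
        note_id=note_id,
        category=category,
        positive=gold_text is not None,
        relaxed_precision=p,
        relaxed_recall=r,
        relaxed_f1=f1,
        strict_f1=strict_f1(gold, pred_text),
        scenario=classify_scenario(p, r),
    )


@dataclass
class ScoreTable:
    """Per-category macro averages mirroring the headline results layout:
    relaxed metrics and strict F1 over positive notes, strict F1 over
    negative notes, and strict F1 combined over all notes (the mean over
    all notes, not the mean of the two subgroup means)."""

    table: pd.DataFrame

    def __str__(self) -> str:  # delimited report
        return self.table.to_string(float_format=lambda v: f"{v:.4f}")


def macro_table(records: Sequence[EvalRecord]) -> ScoreTable:
    """Macro-average the per-note records within each category."""
    rows = []
    for cat in SUDCategory:
        recs = [r for r in records if r.category == cat]
        if not recs:
            log.warning("category %s has no scored notes; omitted", cat.value)
            continue
        pos = [r for r in recs if r.positive]
        neg = [r for r in recs if not r.positive]
        rows.append(
            {
                "category": cat.value,
                "n_pos": len(pos),
                "n_neg": len(neg),
                "strict_f1_pos": np.mean([r.strict_f1 for r in pos]) if pos else np.nan,
                "relaxed_f1_pos": np.mean([r.relaxed_f1 for r in pos]) if pos else np.nan,
                "relaxed_recall_pos": np.mean([r.relaxed_recall for r in pos]) if pos else np.nan,
                "relaxed_precision_pos": np.mean([r.relaxed_precision for r in pos]) if pos else np.nan,
                "strict_f1_neg": np.mean([r.strict_f1 for r in neg]) if neg else np.nan,
                "strict_f1_combined": np.mean([r.strict_f1 for r in recs]),
            }
        )
    columns = [
        "category", "n_pos", "n_neg", "strict_f1_pos", "relaxed_f1_pos",
        "relaxed_recall_pos", "relaxed_precision_pos", "strict_f1_neg",
        "strict_f1_combined",
    ]
    return ScoreTable(pd.DataFrame(rows, columns=columns).set_index("category"))


def scenario_histogram(records: Sequence[EvalRecord]) -> pd.DataFrame:
    """Counts of the five error scenarios per category over positive notes."""
    scenarios: list[Scenario] = ["strict_match", "recall_only", "precision_only", "no_match", "other"]
    rows = {}
    for cat in SUDCategory:
        pos = [r for r in records if r.category == cat and r.positive]
        if pos:
            counts = Counter(r.scenario for r in pos)
            rows[cat.value] = {s: counts.get(s, 0) for s in scenarios}
    return pd.DataFrame.from_dict(rows, orient="index", columns=scenarios).fillna(0).astype(int)


def _stars(p_value: float) -> str:
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def candidate_count_report(
    note_lengths: Mapping[str, int],
    counts: Mapping[tuple[str, SUDCategory], int],
) -> pd.DataFrame:
    """Per-category candidate-count distribution and length correlation.

    For each category: the fraction of notes with more than one surviving
    candidate answer, the Pearson correlation between note length (tokens)
    and candidate count with its two-sided significance (stars at
    0.05/0.01/0.001), and the stacked distribution of counts.  Zero variance
    in either variable leaves the coefficient undefined (NaN).
    """
    rows = {}
    for cat in SUDCategory:
        pairs = [
            (note_lengths[nid], k)
            for (nid, c), k in counts.items()
            if c == cat and nid in note_lengths
        ]
        if not pairs:
            continue
        lengths = np.array([p[0] for p in pairs], float)
        ks = np.array([p[1] for p in pairs], float)
        if len(pairs) >= 3 and lengths.std() > 0 and ks.std() > 0:
            r, p_value = stats.pearsonr(lengths, ks)
        else:
            r, p_value = np.nan, np.nan
        dist = Counter(int(k) for k in ks if k > 1)
        rows[cat.value] = {
            "n_notes": len(pairs),
            "frac_multi_candidate": float(np.mean(ks > 1)),
            "pearson_r": r,
            "p_value": p_value,
            "significance": _stars(p_value) if np.isfinite(p_value) else "",
            "count_distribution": dict(sorted(dist.items())),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
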