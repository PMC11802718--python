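"""Four-stage post-processing of per-chunk candidate answers.

Generated text is only trusted after a filtering cascade reduces the
per-chunk candidates for one (note, category) pair to a single answer:

(i)   drop candidates lacking any of the category's substance terms;
(ii)  drop candidates lacking a use-disorder phrase *after* the substance
      name;
(iii) drop candidates whose lexicon-bearing content is not grounded in the
      note: the candidate must share at least one maximal common substring
      of >= ``min_len`` characters (default 5, the length of the shortest
      real-world diagnosis string "mj ud") with the note, and the union of
      that shared material must itself pass (i)-(ii);
(iv)  if more than one distinct candidate survives, pick the one whose
      embedding is closest (minimum Euclidean distance by default) to the
      category's proxy ground-truth phrase.

Filtered and unanswerable candidates are replaced by the sentinel.  Steps
(i)-(iii) are applied only to candidates that do not already contain the
sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .embedding import EmbedderContract, cosine_distance, euclidean_distance
from .extraction import UNANSWERABLE, CandidateAnswer, is_unanswerable
from .lexicon import CategoryLexicon, SUDCategory, contains_disorder, contains_substance, normalize

log = logging.getLogger(__name__)

SelectionMethod = Literal[
    "single_survivor", "proxy_embedding", "all_filtered", "all_unanswerable", "regex"
]


@dataclass(frozen=True)
class FinalAnswer:
    """The post-processed single answer for one (note, category) pair."""

    note_id: str
    category: SUDCategory
    text: str  # span string, or the unanswerable sentinel
    selection_method: SelectionMethod
    n_candidates: int = 0
    n_survivors: int = 0
    filtered: tuple[str, ...] = field(default=())  # audit trail of removed texts


def _supported_mask(cand: str, note: str, min_len: int) -> np.ndarray:
    """Boolean mask over ``cand`` chars covered by a common substring of
    length >= min_len shared with ``note`` (both already normalised)."""
    m = len(cand)
    mask = np.zeros(m, dtype=bool)
    k = 0
    for i in range(m):
        if k:
            k -= 1  # cand[i:i+k] still occurs in note (substring closure)
        while i + k < m and note.find(cand[i : i + k + 1]) != -1:
            k += 1
        if k >= min_len:
            mask[i : i + k] = True
    return mask


def filter_substring_support(
    candidate: str, note_text: str, lex: CategoryLexicon, min_len: int = 5
) -> bool:
    """Grounding filter (iii).

    True iff the candidate and the note share at least one maximal common
    substring of >= ``min_len`` characters and the concatenation of the
    candidate's shared (supported) portions itself satisfies filters
    (i)-(ii).  A false result signals a hallucination-style mismatch: the
    lexicon-bearing part of the answer does not come from the note.
    """
    cand = normalize(candidate)
    note = normalize(note_text)
    if not cand or not note:
        return False
    mask = _supported_mask(cand, note, min_len)
    if not mask.any():
        return False
    # Concatenate supported runs, separated by spaces so no spurious terms
    # form across run boundaries; order within the candidate is preserved.
    pieces: list[str] = []
    i = 0
    m = len(cand)
    while i < m:
        if mask[i]:
            j = i
            while j < m and mask[j]:
                j += 1
            pieces.append(cand[i:j])
            i = j
        else:
            i += 1
    supported = " ".join(pieces)
    return contains_substance(supported, lex) and contains_disorder(supported, lex)


def apply_filters(
    candidates: Sequence[CandidateAnswer],
    note_text: str,
    lex: CategoryLexicon,
    min_len: int = 5,
) -> list[CandidateAnswer]:
    """Apply filters (i)-(iii), keeping survivors in original chunk order."""
    survivors = []
    for c in candidates:
        if is_unanswerable(c.text):
            continue
        if not contains_substance(c.text, lex):
            continue
        if not contains_disorder(c.text, lex):
            continue
        if not filter_substring_support(c.text, note_text, lex, min_len):
            continue
        survivors.append(c)
    return survivors


def expand_proxy(proxy: str) -> list[str]:
    """Expand slash alternatives in a proxy phrase.

    "cannabis use disorder/dependence" -> ["cannabis use disorder",
    "cannabis use dependence"]: each token containing "/" contributes one
    variant per alternative.  A candidate is scored by its best (minimum)
    distance over variants.
    """
    variants = [""]
    for tok in proxy.split():
        alts = tok.split("/") if "/" in tok else [tok]
        variants = [f"{v} {a}".strip() for v in variants for a in alts]
    return variants or [proxy]


def select_by_proxy(
    candidates: Sequence[CandidateAnswer],
    proxy: str,
    embedder: EmbedderContract,
    metric: Literal["euclidean", "cosine"] = "euclidean",
) -> CandidateAnswer:
    """Pick the candidate closest to the proxy ground truth in embedding space.

    Minimum Euclidean distance by default (equivalently, highest
    negative-distance similarity score); cosine distance behind the
    ``metric`` switch.  Ties break to the lowest chunk index, and embedder
    failures fall back to the lowest chunk index with a warning.
    """
    if len(candidates) < 2:
        raise ValueError("proxy selection requires >= 2 candidates")
    dist = euclidean_distance if metric == "euclidean" else cosine_distance
    fallback = min(candidates, key=lambda c: c.chunk_index)
    try:
        proxy_vecs = [embedder.embed(v) for v in expand_proxy(proxy)]
        scored = [
            (min(dist(embedder.embed(c.text), pv) for pv in proxy_vecs), c.chunk_index, c)
            for c in candidates
        ]
    except Exception:  # noqa: BLE001 - selection must not abort the run
        log.warning("embedder failed; falling back to lowest chunk index", exc_info=True)
        return fallback
    return min(scored, key=lambda t: (t[0], t[1]))[2]


def postprocess_note(
    candidates: Sequence[CandidateAnswer],
    note_text: str,
    lex: CategoryLexicon,
    embedder: EmbedderContract,
    min_len: int = 5,
    metric: Literal["euclidean", "cosine"] = "euclidean",
    dedup: bool = True,
) -> FinalAnswer:
    """Reduce the per-chunk candidates of one (note, category) to one answer.

    Duplicate survivor strings from overlapping chunks are collapsed before
    counting (first occurrence kept), so a long note whose single diagnosis
    appears in several windows does not trigger proxy selection.
    """
    if candidates:
        note_id = candidates[0].note_id
        category = candidates[0].category
        if any(c.note_id != note_id or c.category != category for c in candidates):
            raise ValueError("candidates must all belong to one (note, category)")
    else:
        note_id, category = "", lex.category

    n = len(candidates)
    answerable = [c for c in candidates if not is_unanswerable(c.text)]
    if not answerable:
        return FinalAnswer(note_id, lex.category, UNANSWERABLE, "all_unanswerable", n, 0)

    survivors = apply_filters(candidates, note_text, lex, min_len)
    filtered = tuple(c.text for c in answerable if c not in survivors)
    if dedup:
        seen: set[str] = set()
        unique = []
        for c in survivors:
            if c.text not in seen:
                seen.add(c.text)
                unique.append(c)
        survivors = unique

    if not survivors:
        return FinalAnswer(
            note_id, lex.category, UNANSWERABLE, "all_filtered", n, 0, filtered
        )
    if len(survivors) == 1:
        return FinalAnswer(
            note_id, lex.category, survivors[0].text, "single_survivor", n, 1, filtered
        )
    best = select_by_proxy(survivors, lex.proxy_ground_truth, embedder, metric)
    return FinalAnswer(
        note_id, lex.category, best.text, "proxy_embedding", n, len(survivors), filtered
    )
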