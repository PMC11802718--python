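"""Synthetic corpus generator: fidelity to the documented data structure."""

import json
import math
from collections import Counter

import numpy as np
import pytest

from sudspan.lexicon import SUDCategory, lexicon_map
from sudspan.postprocess import filter_substring_support
from sudspan.lexicon import contains_disorder, contains_substance
from sudspan.synthetic import (
    ATTESTED_VARIANTS,
    CorpusSpec,
    available_styles,
    dev_test_split,
    generate_corpus,
    generate_note,
    render_diagnosis,
)


def test_same_seed_is_byte_identical():
    spec = CorpusSpec(n_notes=50, seed=3)
    a = generate_corpus(spec)
    b = generate_corpus(spec)
    assert json.dumps(a) == json.dumps(b)


def test_different_seeds_differ():
    a = generate_corpus(CorpusSpec(n_notes=50, seed=3))
    b = generate_corpus(CorpusSpec(n_notes=50, seed=4))
    assert json.dumps(a) != json.dumps(b)


def test_empty_corpus():
    notes, gold = generate_corpus(CorpusSpec(n_notes=0))
    assert notes == [] and gold == []


def test_positive_fractions_within_three_binomial_sds(corpus577):
    spec, notes, gold = corpus577
    n = spec.n_notes
    counts = Counter(g["category"] for g in gold)
    for cat, p in spec.prevalence.items():
        sd = math.sqrt(n * p * (1 - p))
        assert abs(counts[cat.value] - n * p) <= 3 * sd, cat


def test_prevalence_defaults_span_study_range(corpus577):
    spec, _, _ = corpus577
    values = list(spec.prevalence.values())
    assert min(values) == 0.03 and max(values) == 0.33
    assert np.mean(values) == pytest.approx(0.10, abs=1e-9)


def test_forced_prevalence_marks_every_note():
    spec = CorpusSpec(n_notes=40, seed=1)
    spec.prevalence[SUDCategory.alcohol] = 1.0
    notes, gold = generate_corpus(spec)
    alcohol_notes = {g["note_id"] for g in gold if g["category"] == "alcohol"}
    assert alcohol_notes == {n["note_id"] for n in notes}
    by_id = {n["note_id"]: n["text"] for n in notes}
    for g in gold:
        assert g["span_text"] in by_id[g["note_id"]]


def test_comorbidity_rate_matches_spec(corpus577):
    spec, _, gold = corpus577
    per_note = Counter(g["note_id"] for g in gold)
    frac = sum(1 for v in per_note.values() if v >= 2) / len(per_note)
    assert frac == pytest.approx(spec.comorbidity_rate, abs=0.02)


def test_note_length_distribution(corpus577):
    spec, notes, _ = corpus577
    lengths = [len(n["text"].split()) for n in notes]
    assert min(lengths) >= spec.length_min
    assert max(lengths) <= spec.length_max
    assert abs(np.median(lengths) - spec.length_median) <= 0.2 * spec.length_median


def test_gold_spans_verbatim_and_filter_compatible(corpus577):
    """Every gold span occurs verbatim in its note and passes the
    post-processing filters (i)-(iii), so an oracle extraction of the gold
    span always survives post-processing."""
    _, notes, gold = corpus577
    lexicons = lexicon_map()
    by_id = {n["note_id"]: n["text"] for n in notes}
    for g in gold:
        note = by_id[g["note_id"]]
        lex = lexicons[SUDCategory(g["category"])]
        span = g["span_text"]
        assert span in note
        assert contains_substance(span, lex)
        assert contains_disorder(span, lex)
        assert filter_substring_support(span, note, lex)


def test_no_span_truncation_collides_with_another_span(corpus577):
    """No token-boundary prefix/suffix truncation of one gold span equals a
    different gold span of the same category: a chunk window cutting a span
    cannot surface a second spurious oracle candidate."""
    _, _, gold = corpus577
    by_cat: dict[str, set[str]] = {}
    for g in gold:
        by_cat.setdefault(g["category"], set()).add(g["span_text"])
    for spans in by_cat.values():
        for span in spans:
            toks = span.split()
            truncations = {" ".join(toks[i:]) for i in range(1, len(toks))}
            truncations |= {" ".join(toks[:i]) for i in range(1, len(toks))}
            assert not (truncations & spans), span


def test_each_positive_category_has_exactly_one_gold_entry(corpus577):
    _, _, gold = corpus577
    pairs = [(g["note_id"], g["category"]) for g in gold]
    assert len(pairs) == len(set(pairs))


def test_all_attested_variants_are_producible():
    """Each documented real-world diagnosis variant is emitted by its
    (category, style) grammar within a bounded number of seeded draws."""
    rng = np.random.default_rng(2024)
    for category, style, target in ATTESTED_VARIANTS:
        seen = False
        for _ in range(10_000):
            if render_diagnosis(category, style, rng) == target:
                seen = True
                break
        assert seen, target


def test_unknown_style_raises():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="unknown style"):
        render_diagnosis(SUDCategory.alcohol, "haiku", rng)
    with pytest.raises(ValueError, match="not available"):
        render_diagnosis(SUDCategory.caffeine, "slash_combined", rng)


def test_available_styles_cover_the_grammar():
    styles = set()
    for cat in SUDCategory:
        styles.update(available_styles(cat))
    assert styles == {
        "plain",
        "abbreviated",
        "checkbox",
        "remission",
        "parenthetical",
        "slash_combined",
        "unspecified",
    }


def test_problem_list_distractor_mentions_non_gold_category():
    from sudspan.synthetic import _SUBSTANCE_NAME

    name_to_cat = {v: k for k, v in _SUBSTANCE_NAME.items()}
    spec = CorpusSpec(n_notes=120, seed=9, problem_list_rate=1.0)
    notes, gold = generate_corpus(spec)
    positive = {(g["note_id"], g["category"]) for g in gold}
    seen = 0
    for note in notes:
        if "previous encounters problem list includes" in note["text"]:
            seen += 1
            line = next(
                ln for ln in note["text"].splitlines() if ln.startswith("{x}")
            )
            substance = line.removeprefix("{x} ").removesuffix(" abuse")
            cat = name_to_cat[substance]
            assert (note["note_id"], cat.value) not in positive
    assert seen > 0


def test_comorbid_note_places_spans_in_one_diagnosis_block(corpus577):
    _, notes, gold = corpus577
    per_note = Counter(g["note_id"] for g in gold)
    comorbid = [nid for nid, k in per_note.items() if k >= 2]
    assert comorbid
    by_id = {n["note_id"]: n["text"] for n in notes}
    for nid in comorbid[:10]:
        text = by_id[nid]
        spans = {g["span_text"] for g in gold if g["note_id"] == nid}
        dx_lines = [ln for ln in text.splitlines() if ln.startswith("dx: ")]
        # spans are adjacent dx lines of a single diagnoses block (slash
        # spans document several categories on one line)
        assert len(dx_lines) == len(spans)
        assert text.count("assessment / diagnoses:") == 1
        for span in spans:
            assert f"dx: {span}" in text


def test_dev_test_split_by_patient(corpus577):
    _, notes, _ = corpus577
    dev, test = dev_test_split(notes, dev_fraction=0.10, seed=0)
    assert set(dev).isdisjoint(test)
    assert len(dev) + len(test) == len(notes)
    by_id = {n["note_id"]: n["patient_id"] for n in notes}
    dev_patients = {by_id[i] for i in dev}
    test_patients = {by_id[i] for i in test}
    assert dev_patients.isdisjoint(test_patients)
    assert 0.05 <= len(dev) / len(notes) <= 0.15


def test_notes_to_patients_ratio_slightly_above_one(corpus577):
    _, notes, _ = corpus577
    patients = {n["patient_id"] for n in notes}
    assert len(notes) - len(patients) == 3  # 577 notes from 574 patients


def test_generate_note_without_forced_categories_uses_prevalence():
    spec = CorpusSpec(seed=0)
    rng = np.random.default_rng(0)
    n_pos = 0
    for i in range(300):
        _, gold = generate_note(spec, rng, note_id=f"n{i}")
        n_pos += len(gold)
    # expected positives per note = sum of prevalences = 1.10
    assert 0.8 <= n_pos / 300 <= 1.4
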