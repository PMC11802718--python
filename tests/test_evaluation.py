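"""Strict/relaxed scoring, scenarios, macro tables and the correlation report."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sudspan.evaluation import (
    answer_tokens,
    candidate_count_report,
    classify_scenario,
    macro_table,
    relaxed_scores,
    scenario_histogram,
    score_answer,
    strict_f1,
)
from sudspan.lexicon import SUDCategory


class TestAnswerTokens:
    def test_isolates_punctuation_but_keeps_slash(self):
        assert answer_tokens("severe etoh use d/o") == Counter(
            ["severe", "etoh", "use", "d/o"]
        )
        assert answer_tokens("alcohol use disorder, severe") == Counter(
            ["alcohol", "use", "disorder", ",", "severe"]
        )

    def test_sentinel_and_empty_map_to_empty_multiset(self):
        assert answer_tokens("unanswerable") == Counter()
        assert answer_tokens("the answer is Unanswerable.") == Counter()
        assert answer_tokens("") == Counter()

    def test_multiset_flag_collapses_repeats(self):
        assert answer_tokens("use use use")["use"] == 3
        assert answer_tokens("use use use", multiset=False)["use"] == 1


class TestRelaxedScores:
    def test_identity_scores_perfect(self):
        g = answer_tokens("severe etoh use d/o")
        assert relaxed_scores(g, g) == (1.0, 1.0, 1.0)

    def test_extra_prediction_token_costs_precision(self):
        g = answer_tokens("severe etoh use d/o")
        p = answer_tokens("severe etoh use d/o daily")
        precision, recall, f1 = relaxed_scores(g, p)
        assert (precision, recall) == (0.8, 1.0)
        assert f1 == pytest.approx(0.8889, abs=1e-4)

    def test_empty_conventions(self):
        empty = Counter()
        some = answer_tokens("alcohol use disorder")
        assert relaxed_scores(empty, empty) == (1.0, 1.0, 1.0)
        assert relaxed_scores(some, empty) == (1.0, 0.0, 0.0)
        assert relaxed_scores(empty, some) == (0.0, 1.0, 0.0)

    @given(
        gold=st.lists(st.sampled_from("abcdef"), max_size=8),
        pred=st.lists(st.sampled_from("abcdef"), max_size=8),
    )
    def test_against_bruteforce_counter_and_symmetry(self, gold, pred):
        g, p = Counter(gold), Counter(pred)
        tp = sum(min(g[t], p[t]) for t in set(g) | set(p))
        fn = sum(g.values()) - tp
        fp = sum(p.values()) - tp
        precision, recall, f1 = relaxed_scores(g, p)
        assert 0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0 and 0.0 <= f1 <= 1.0
        expected_p = tp / (tp + fp) if tp + fp else 1.0
        expected_r = tp / (tp + fn) if tp + fn else 1.0
        assert precision == pytest.approx(expected_p, abs=1e-12)
        assert recall == pytest.approx(expected_r, abs=1e-12)
        # swapping gold and prediction swaps precision and recall
        p2, r2, _ = relaxed_scores(p, g)
        assert p2 == pytest.approx(recall, abs=1e-12)
        assert r2 == pytest.approx(precision, abs=1e-12)


class TestStrictF1:
    def test_exact_match_scores_one(self):
        assert strict_f1("severe etoh use d/o", "severe etoh use d/o") == 1.0

    def test_containment_is_not_exact_match(self):
        assert strict_f1("severe etoh use d/o", "dx severe etoh use d/o today") == 0.0

    def test_no_sud_conventions(self):
        assert strict_f1("", "unanswerable") == 1.0  # no tokens generated
        assert strict_f1("", "alcohol use disorder") == 0.0  # false positives
        assert strict_f1("severe etoh use d/o", "unanswerable") == 0.0

    def test_normalisation_is_casefold_and_whitespace(self):
        assert strict_f1("Severe  ETOH use d/o", "severe etoh use d/o") == 1.0

    def test_strict_match_implies_relaxed_perfect(self):
        for g, p in [("severe etoh use d/o", "severe  ETOH use d/o")]:
            if strict_f1(g, p) == 1.0:
                assert relaxed_scores(answer_tokens(g), answer_tokens(p))[2] == 1.0


@pytest.mark.parametrize(
    ("precision", "recall", "expected"),
    [
        (1.0, 1.0, "strict_match"),
        (0.8, 1.0, "recall_only"),
        (1.0, 0.7, "precision_only"),
        (0.0, 0.0, "no_match"),
        (0.5, 0.5, "other"),
    ],
)
def test_classify_scenario(precision, recall, expected):
    assert classify_scenario(precision, recall) == expected


class TestMacroTable:
    def _records(self, specs):
        return [
            score_answer(f"n{i}", cat, gold, pred)
            for i, (cat, gold, pred) in enumerate(specs)
        ]

    def test_positive_strict_macro_is_mean(self):
        recs = self._records(
            [
                (SUDCategory.alcohol, "etoh use d/o", "etoh use d/o"),
                (SUDCategory.alcohol, "etoh use d/o", "something else"),
            ]
        )
        table = macro_table(recs).table
        assert table.loc["alcohol", "strict_f1_pos"] == 0.5

    def test_all_negative_corpus_scores_one(self):
        recs = self._records(
            [(SUDCategory.cocaine, None, "unanswerable") for _ in range(5)]
        )
        table = macro_table(recs).table
        assert table.loc["cocaine", "strict_f1_neg"] == 1.0

    def test_combined_is_mean_over_all_notes_not_subgroup_means(self):
        recs = self._records(
            [
                (SUDCategory.alcohol, "etoh use d/o", "etoh use d/o"),  # pos, 1.0
                (SUDCategory.alcohol, None, "unanswerable"),  # neg, 1.0
                (SUDCategory.alcohol, None, "spurious text"),  # neg, 0.0
            ]
        )
        table = macro_table(recs).table
        assert table.loc["alcohol", "strict_f1_combined"] == pytest.approx(2 / 3)
        assert table.loc["alcohol", "strict_f1_neg"] == 0.5

    def test_single_note_combined_equals_its_score(self):
        recs = self._records([(SUDCategory.opioid, "opioid use d/o", "opioid use d/o")])
        assert macro_table(recs).table.loc["opioid", "strict_f1_combined"] == 1.0

    def test_empty_category_omitted(self):
        recs = self._records([(SUDCategory.alcohol, None, "unanswerable")])
        assert list(macro_table(recs).table.index) == ["alcohol"]

    def test_scenario_histogram_counts_positive_notes(self):
        recs = self._records(
            [
                (SUDCategory.alcohol, "etoh use d/o", "etoh use d/o"),
                (SUDCategory.alcohol, "etoh use d/o", "dx etoh use d/o now"),
                (SUDCategory.alcohol, None, "unanswerable"),
            ]
        )
        hist = scenario_histogram(recs)
        assert hist.loc["alcohol", "strict_match"] == 1
        assert hist.loc["alcohol", "recall_only"] == 1
        assert hist.loc["alcohol"].sum() == 2  # negatives excluded


class TestCandidateCountReport:
    def test_zero_variance_leaves_r_undefined(self):
        lengths = {f"n{i}": 100 + i for i in range(5)}
        counts = {(f"n{i}", SUDCategory.alcohol): 1 for i in range(5)}
        report = candidate_count_report(lengths, counts)
        assert np.isnan(report.loc["alcohol", "pearson_r"])

    def test_perfect_linear_relation(self):
        lengths = {f"n{i}": 10 * (i + 1) for i in range(10)}
        counts = {(f"n{i}", SUDCategory.alcohol): i + 1 for i in range(10)}
        report = candidate_count_report(lengths, counts)
        assert report.loc["alcohol", "pearson_r"] == pytest.approx(1.0)
        assert report.loc["alcohol", "significance"] == "***"

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(42)
        lengths_arr = rng.integers(20, 2000, size=20).astype(float)
        counts_arr = rng.integers(1, 5, size=20).astype(float)
        lengths = {f"n{i}": int(v) for i, v in enumerate(lengths_arr)}
        counts = {
            (f"n{i}", SUDCategory.cannabis): int(v) for i, v in enumerate(counts_arr)
        }
        report = candidate_count_report(lengths, counts)
        x, y = lengths_arr, counts_arr
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert report.loc["cannabis", "pearson_r"] == pytest.approx(expected, abs=1e-12)

    def test_multi_candidate_fraction(self):
        lengths = {"a": 100, "b": 900, "c": 1500}
        counts = {
            ("a", SUDCategory.alcohol): 1,
            ("b", SUDCategory.alcohol): 2,
            ("c", SUDCategory.alcohol): 3,
        }
        report = candidate_count_report(lengths, counts)
        assert report.loc["alcohol", "frac_multi_candidate"] == pytest.approx(2 / 3)
        assert report.loc["alcohol", "count_distribution"] == {2: 1, 3: 1}
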