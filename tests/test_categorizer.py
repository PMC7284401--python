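"""Multi-label assignment, frequency percentages, and the overlap matrix."""

from itertools import combinations

import numpy as np
import pytest

from ibd_dialog.categorizer import (
    categorize_corpus,
    categorize_line,
    frequency_report,
    overlap_matrix,
    percent_of,
)
from ibd_dialog.dialog_io import DialogRecord, Direction
from ibd_dialog.labels import label_code
from ibd_dialog.text_prep import normalize_tokens, tokenize

# --- independent brute-force oracles -------------------------------------


def brute_force_labels(content, lexicon, stop_words):
    """Test every (category, keyword) pair via padded-string containment."""
    filtered = [t for t in normalize_tokens(content) if t not in stop_words]
    padded = f" {' '.join(normalize_tokens(content))} "
    codes = set()
    for cat in lexicon.categories:
        if cat.fallback:
            continue
        for kw in cat.keywords:
            hit = f" {kw} " in padded if " " in kw else kw in filtered
            if hit:
                codes.add(cat.code)
    return frozenset(codes) if codes else frozenset({lexicon.fallback_code})


def brute_force_overlap(labels, lexicon):
    codes = list(lexicon.non_fallback_codes)
    m = np.zeros((len(codes), len(codes)), dtype=int)
    pos = {c: i for i, c in enumerate(codes)}
    informative = [ls for ls in labels.values() if lexicon.fallback_code not in ls]
    for i, a in enumerate(codes):
        m[i, i] = sum(1 for ls in informative if ls == frozenset({a}))
    for a, b in combinations(codes, 2):
        n_ab = sum(1 for ls in informative if a in ls and b in ls)
        m[pos[a], pos[b]] = m[pos[b], pos[a]] = n_ab
    return m


def _record(i, content):
    return DialogRecord(
        identifier=f"m{i:03d}",
        first_name=None,
        last_name=None,
        timestamp="2018-01-01T00:00:00",
        direction=Direction.PATIENT_TO_HCP,
        content=content,
    )


# --- categorize_line ------------------------------------------------------


class TestCategorizeLine:
    def _labels(self, content, lexicon):
        return categorize_line(tokenize(content), content, lexicon)

    def test_medication_keyword_assigns_medications(self, lexicon):
        assert self._labels("took tylenol last night", lexicon) == frozenset({2})

    def test_no_keyword_falls_back_to_miscellaneous(self, lexicon):
        assert self._labels("just checking in with a note", lexicon) == frozenset({8})

    def test_union_over_categories_with_canonical_code(self, lexicon):
        labels = self._labels("the pain got worse after the new dose", lexicon)
        assert labels == frozenset({1, 2})
        assert label_code(labels) == "12"

    def test_phrase_keyword_matches_through_stop_words(self, lexicon):
        # "follow up" survives even though "up" is a stop word absent from the bag
        assert self._labels("can we follow up next week", lexicon) == frozenset({3})

    def test_phrase_does_not_match_non_contiguously(self, toy_lexicon):
        # "red ... apple" is not the phrase "red apple", but "apple" alone still hits
        labels = self._labels("red drum apple", toy_lexicon)
        assert labels == frozenset({1})
        assert self._labels("red drum", toy_lexicon) == frozenset({toy_lexicon.fallback_code})

    def test_keyword_monotonicity_adding_a_keyword_never_drops_a_count(self, lexicon):
        from ibd_dialog.lexicon import build_lexicon

        contents = [
            "my insurance denied the claim",
            "questions about my averages",
            "the infusion went fine",
            "need a refill before the visit",
        ]
        records = [_record(i, c) for i, c in enumerate(contents)]
        base_count = sum(
            1 for ls in categorize_corpus(records, lexicon).values() if 4 in ls
        )
        entries = [
            {
                "code": c.code,
                "name": c.name,
                "fallback": c.fallback,
                "keywords": sorted(c.keywords) + (["averages"] if c.code == 4 else []),
            }
            for c in lexicon.categories
        ]
        widened = build_lexicon(entries)
        new_count = sum(
            1 for ls in categorize_corpus(records, widened).values() if 4 in ls
        )
        assert new_count >= base_count
        assert new_count == base_count + 1  # "averages" line now reaches labs


# --- frequency_report -----------------------------------------------------


class TestFrequencyReport:
    def test_overlapping_labels_sum_past_100_percent(self):
        labels = {"a": frozenset({1}), "b": frozenset({1, 2}), "c": frozenset({2})}
        report = frequency_report(labels)
        assert report.per_category[1] == (2, 66.67)
        assert report.per_category[2] == (2, 66.67)
        assert sum(p for _, p in report.per_category.values()) > 100

    @pytest.mark.parametrize(
        ("count", "denom", "expected"),
        [(2033, 6193, 32.83), (5574, 6193, 90.00), (624, 6193, 10.08), (1, 3, 33.33)],
    )
    def test_percent_is_half_up_rounded_to_two_decimals(self, count, denom, expected):
        assert percent_of(count, denom) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            frequency_report({})

    def test_counts_bounded_by_denominator(self, lexicon):
        labels = {f"m{i}": frozenset({1}) for i in range(10)}
        report = frequency_report(labels, lexicon)
        assert report.denominator == 10
        assert all(count <= 10 for count, _ in report.per_category.values())
        assert report.per_category[1] == (10, 100.0)


# --- overlap_matrix -------------------------------------------------------


class TestOverlapMatrix:
    def test_pair_and_solo_counting(self, toy_lexicon):
        labels = {"x": frozenset({1, 2}), "y": frozenset({1})}
        m = overlap_matrix(labels, toy_lexicon)
        assert m.loc[1, 2] == m.loc[2, 1] == 1
        assert m.loc[1, 1] == 1
        assert m.loc[2, 2] == 0

    def test_all_single_category_gives_diagonal_only(self, toy_lexicon):
        labels = {f"m{i}": frozenset({1 + i % 3}) for i in range(9)}
        m = overlap_matrix(labels, toy_lexicon)
        assert np.all(m.values == np.diag(np.diag(m.values)))
        assert np.trace(m.values) == 9

    def test_triple_label_increments_each_pair_not_the_diagonal(self, toy_lexicon):
        m = overlap_matrix({"x": frozenset({1, 2, 3})}, toy_lexicon)
        expected = brute_force_overlap({"x": frozenset({1, 2, 3})}, toy_lexicon)
        assert np.array_equal(m.values, expected)
        assert np.trace(m.values) == 0

    def test_fallback_lines_never_appear(self, toy_lexicon):
        labels = {"x": frozenset({4}), "y": frozenset({1})}
        m = overlap_matrix(labels, toy_lexicon)
        assert m.values.sum() == 1  # only the solo alpha line

    def test_conservation_of_lines(self, lexicon):
        from ibd_dialog.synthetic import SyntheticSpec, generate_corpus

        corpus = generate_corpus(
            SyntheticSpec(n_lines=800, greeting_fraction=0, automated_fraction=0, seed=5),
            lexicon,
        )
        labels = corpus.labeled_truth()
        m = overlap_matrix(labels, lexicon)
        solo = int(np.trace(m.values))
        multi = sum(
            1
            for ls in labels.values()
            if lexicon.fallback_code not in ls and len(ls) > 1
        )
        fallback = sum(1 for ls in labels.values() if lexicon.fallback_code in ls)
        assert solo + multi + fallback == len(labels)


# --- oracle equivalence on random corpora ---------------------------------


def test_categorizer_and_overlap_match_brute_force_on_random_corpora(lexicon, stop_words):
    rng = np.random.default_rng(2024)
    pool = [kw for c in lexicon.categories for kw in sorted(c.keywords)]
    pool += [f"noise{i}" for i in range(20)] + ["the", "my", "a"]
    for _ in range(30):
        n = int(rng.integers(1, 51))
        records = []
        for i in range(n):
            words = [pool[int(rng.integers(len(pool)))] for _ in range(int(rng.integers(1, 9)))]
            records.append(_record(i, " ".join(words)))
        labels = categorize_corpus(records, lexicon, stop_words)
        for rec in records:
            assert labels[rec.identifier] == brute_force_labels(rec.content, lexicon, stop_words)
        assert np.array_equal(
            overlap_matrix(labels, lexicon).values, brute_force_overlap(labels, lexicon)
        )


def test_categorize_corpus_empty_and_constant_cases(lexicon):
    assert categorize_corpus([], lexicon) == {}
    records = [_record(i, "still having diarrhea daily") for i in range(7)]
    labels = categorize_corpus(records, lexicon)
    assert all(ls == frozenset({1}) for ls in labels.values())
    assert frequency_report(labels, lexicon).per_category[1] == (7, 100.0)
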