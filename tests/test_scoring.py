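"""Per-publication domain scores and corpus-relative quality banding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mndprio.records import EFFICACY_CATEGORIES, SAFETY_CATEGORIES
from mndprio.registry import checklist_items
from mndprio.scoring import (
    efficacy_points,
    efficacy_score,
    quality_band,
    quality_raw,
    safety_score,
    score_corpus,
    study_size_score,
)


class TestSafetyAndEfficacyPoints:
    @pytest.mark.parametrize(
        "category,points",
        [
            ("not_described", 1),
            ("susar_or_mortality", 1),
            ("sae_only", 2),
            ("ae_only", 3),
            ("none_reported", 4),
        ],
    )
    def test_safety_points(self, category, points):
        assert safety_score(category) == points

    @pytest.mark.parametrize(
        "category,points",
        [
            ("not_presented", 1),
            ("significant_worsening", 1),
            ("neutral", 2),
            ("nonsignificant_improvement", 3),
            ("significant_improvement", 4),
        ],
    )
    def test_efficacy_points(self, category, points):
        assert efficacy_points(category) == points

    def test_total_on_enums(self):
        # every legal token scores within 1..4; anything else raises
        assert {safety_score(c) for c in SAFETY_CATEGORIES} <= set(range(1, 5))
        assert {efficacy_points(c) for c in EFFICACY_CATEGORIES} <= set(range(1, 5))
        with pytest.raises(ValueError):
            safety_score("SAE")
        with pytest.raises(ValueError):
            efficacy_points("improved")


class TestEfficacyScore:
    def test_primary_outcome_wins(self):
        outcomes = {"o1": "neutral", "o2": "significant_improvement"}
        assert efficacy_score("o1", outcomes) == 2.0

    def test_mean_over_outcomes_without_primary(self):
        outcomes = {"o1": "neutral", "o2": "significant_improvement"}
        assert efficacy_score(None, outcomes) == 3.0

    def test_no_outcomes_scores_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert efficacy_score(None, {}) == 1.0

    def test_missing_primary_outcome_raises(self):
        with pytest.raises(ValueError):
            efficacy_score("o9", {"o1": "neutral"})


class TestQualityRaw:
    def test_all_items_at_maximum(self):
        responses = {}
        for item in checklist_items().values():
            responses[item.item_id] = (
                "yes" if item.response_class in ("binary", "tertiary") else "definitely_yes"
            )
        assert quality_raw(responses) == 21.0

    def test_not_clear_half_points(self):
        responses = {}
        for item in checklist_items().values():
            if item.response_class == "tertiary":
                responses[item.item_id] = "not_clear"
            elif item.response_class == "binary":
                responses[item.item_id] = "no"
            else:
                responses[item.item_id] = "definitely_no"
        assert quality_raw(responses) == 4.0  # 8 tertiary items × 0.5

    def test_probably_yes_three_quarters(self):
        assert quality_raw({"adequate_followup": "probably_yes"}) == 0.75

    def test_na_and_missing_contribute_zero(self):
        assert quality_raw({"adequate_followup": "na"}) == 0.0
        assert quality_raw({}) == 0.0

    def test_illegal_pair_raises(self):
        with pytest.raises(ValueError):
            quality_raw({"adequate_followup": "not_clear"})
        with pytest.raises(ValueError):
            quality_raw({"invented_item": "yes"})


def _band_oracle(raw: dict[str, float]) -> dict[str, int]:
    """Independent banding: percentile thresholds, strictly-exceeded rule."""
    t = np.percentile(list(raw.values()), [25, 50, 75])
    return {k: 1 + sum(v > ti for ti in t) for k, v in raw.items()}


class TestQualityBand:
    def test_four_distinct_values_span_bands(self):
        assert quality_band({"a": 2, "b": 5, "c": 9, "d": 15}) == {
            "a": 1,
            "b": 2,
            "c": 3,
            "d": 4,
        }

    def test_all_equal_scores_band_one(self):
        assert quality_band({"a": 7, "b": 7, "c": 7}) == {"a": 1, "b": 1, "c": 1}

    def test_single_publication_band_one(self):
        assert quality_band({"only": 13.5}) == {"only": 1}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            quality_band({})

    def test_monotone_in_raw_score(self):
        rng = np.random.default_rng(0)
        raw = {f"p{i}": float(x) for i, x in enumerate(rng.uniform(0, 21, 60))}
        bands = quality_band(raw)
        items = sorted(raw, key=raw.get)
        for lo, hi in zip(items, items[1:]):
            assert bands[lo] <= bands[hi]

    def test_distinct_4k_scores_split_evenly(self):
        # with 4k distinct raw scores each band holds exactly k publications
        rng = np.random.default_rng(1)
        for k in (1, 5, 25):
            values = rng.permutation(np.linspace(0, 21, 4 * k))
            raw = {f"p{i}": float(v) for i, v in enumerate(values)}
            bands = list(quality_band(raw).values())
            assert all(bands.count(b) == k for b in (1, 2, 3, 4))

    @given(
        st.lists(
            st.floats(min_value=0, max_value=21, allow_nan=False), min_size=1, max_size=80
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_independent_oracle(self, values):
        raw = {f"p{i}": v for i, v in enumerate(values)}
        assert quality_band(raw) == _band_oracle(raw)


class TestStudySizeScore:
    @pytest.mark.parametrize(
        "n,score",
        [(1, 1), (10, 1), (11, 2), (63, 2), (100, 2), (101, 3), (1000, 3), (1001, 4)],
    )
    def test_bins(self, n, score):
        assert study_size_score(n) == score

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            study_size_score(0)


class TestScoreCorpus:
    def test_composition(self, small_corpus):
        scores = score_corpus(small_corpus)
        assert list(scores.index) == ["p1", "p2", "p3", "p4"]
        p1 = scores.loc["p1"]
        assert p1["safety"] == 3  # AEs only
        assert p1["efficacy"] == 2  # primary outcome neutral
        assert p1["quality_raw"] == 1 + 0.5 + 0.75
        assert p1["study_size"] == 2  # 63 participants
        assert scores.loc["p4", "efficacy"] == 1  # not presented
        assert set(scores["quality"]) <= {1, 2, 3, 4}

    def test_single_publication_corpus_bands_one(self, small_corpus):
        from mndprio.records import Corpus

        solo = Corpus(
            publications=small_corpus.publications.iloc[[0]],
            outcomes=small_corpus.outcomes[small_corpus.outcomes["pub_id"] == "p1"],
            quality=small_corpus.quality[small_corpus.quality["pub_id"] == "p1"],
        )
        assert score_corpus(solo).loc["p1", "quality"] == 1

    def test_order_invariance(self, small_corpus):
        from mndprio.records import Corpus

        shuffled = Corpus(
            publications=small_corpus.publications.iloc[::-1].reset_index(drop=True),
            outcomes=small_corpus.outcomes.iloc[::-1].reset_index(drop=True),
            quality=small_corpus.quality.iloc[::-1].reset_index(drop=True),
            preclinical=small_corpus.preclinical,
        )
        a = score_corpus(small_corpus).sort_index()
        b = score_corpus(shuffled).sort_index()
        assert a.equals(b)

    def test_scores_within_bounds(self, small_corpus):
        scores = score_corpus(small_corpus)
        assert scores["safety"].between(1, 4).all()
        assert scores["efficacy"].between(1, 4).all()
        assert scores["quality_raw"].between(0, 21).all()
        assert scores["study_size"].between(1, 4).all()
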