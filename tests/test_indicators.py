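"""Classification schemes against a brute-force truth-table oracle, plus
rate arithmetic and its pooling/monotonicity properties."""

import numpy as np
import pytest

from cdsseval import (
    ConcordanceCategory,
    Decision,
    HLConcordanceCategory,
    IndicatorResult,
    StudyValidationError,
    TieredRecommendation,
    classify_concordance,
    classify_guideline_conformity,
    classify_hl_concordance,
    indicator_rate,
    is_concordant,
    is_conforming,
    is_hl_concordant,
)

C = ConcordanceCategory
H = HLConcordanceCategory


def oracle_five_way(phys_rec, ref_rec, in_l1, in_l2):
    """Independent enumeration of the five-way scheme from its defining cases."""
    if phys_rec and ref_rec:
        return {(True, False): C.LEVEL_I_MATCH, (False, True): C.LEVEL_II_MATCH,
                (False, False): C.NOT_AVAILABLE}[(in_l1, in_l2)]
    if not phys_rec and not ref_rec:
        return C.NOT_RECOMMENDED_MATCH
    return C.RECOMMEND_DISPUTE


def _structural_cases():
    """All structural (Decision, TieredRecommendation) combinations."""
    ref = TieredRecommendation.of({"l1a", "l1b"}, {"l2a"}, {"l3a"})
    no_ref = TieredRecommendation.not_recommended()
    yield Decision.recommend("l1a"), ref, (True, True, True, False)
    yield Decision.recommend("l2a"), ref, (True, True, False, True)
    yield Decision.recommend("zz"), ref, (True, True, False, False)
    yield Decision.recommend("l3a"), ref, (True, True, False, False)  # Level III -> not available
    yield Decision.not_recommended(), ref, (False, True, False, False)
    yield Decision.recommend("l1a"), no_ref, (True, False, False, False)
    yield Decision.not_recommended(), no_ref, (False, False, False, False)


class TestFiveWayConcordance:
    def test_matches_truth_table_oracle_exhaustively(self):
        seen = set()
        for phys, ref, (pr, rr, l1, l2) in _structural_cases():
            got = classify_concordance(phys, ref)
            assert got == oracle_five_way(pr, rr, l1, l2)
            seen.add(got)
        assert seen == set(C)  # every category reachable, none unclassifiable

    def test_level_one_match_is_set_membership(self):
        ref = TieredRecommendation.of({"AC", "EC"})
        assert classify_concordance(Decision.recommend("AC"), ref) == C.LEVEL_I_MATCH
        assert is_concordant(classify_concordance(Decision.recommend("AC"), ref))

    def test_both_not_recommended_is_concordant(self):
        cat = classify_concordance(
            Decision.not_recommended(), TieredRecommendation.not_recommended())
        assert cat == C.NOT_RECOMMENDED_MATCH and is_concordant(cat)

    def test_unlisted_regimen_is_not_available(self):
        ref = TieredRecommendation.of({"AC"}, {"EC"})
        assert classify_concordance(Decision.recommend("TC+H"), ref) == C.NOT_AVAILABLE

    def test_concordant_set_identity(self):
        assert {c for c in C if is_concordant(c)} == {C.LEVEL_I_MATCH, C.NOT_RECOMMENDED_MATCH}


class TestHighLevelConcordance:
    def test_identical_recommendations_match(self):
        assert classify_hl_concordance(
            Decision.recommend("AC"), Decision.recommend("AC")) == H.RECOMMENDED_MATCH

    def test_cdss_level1_set_membership(self):
        ai = TieredRecommendation.of({"AC", "EC"})
        assert classify_hl_concordance(ai, Decision.recommend("EC")) == H.RECOMMENDED_MATCH
        assert classify_hl_concordance(ai, Decision.recommend("ZZ")) == H.NOT_AVAILABLE

    def test_dispute_when_only_one_recommends(self):
        cat = classify_hl_concordance(Decision.recommend("AC"), Decision.not_recommended())
        assert cat == H.RECOMMEND_DISPUTE and not is_hl_concordant(cat)

    def test_four_way_exhaustive_and_exclusive(self):
        subjects = [Decision.recommend("x"), Decision.not_recommended(),
                    TieredRecommendation.of({"x", "y"}), TieredRecommendation.not_recommended()]
        hls = [Decision.recommend("x"), Decision.recommend("q"), Decision.not_recommended()]
        seen = {classify_hl_concordance(s, hl) for s in subjects for hl in hls}
        assert seen == set(H)

    def test_empty_level1_subject_rejected(self):
        bad = TieredRecommendation.not_recommended()
        object.__setattr__(bad, "recommended", True)  # bypass constructor on purpose
        with pytest.raises(StudyValidationError):
            classify_hl_concordance(bad, Decision.recommend("x"))


class TestGuidelineConformity:
    def test_physician_subject_mirrors_concordance_scheme(self):
        guide = TieredRecommendation.of({"AC"}, {"EC"}, {"XX"})
        for phys in (Decision.recommend("AC"), Decision.recommend("EC"),
                     Decision.recommend("XX"), Decision.not_recommended()):
            assert classify_guideline_conformity(phys, guide) == classify_concordance(phys, guide)

    def test_cdss_level1_intersection_rule(self):
        # CDSS promotes a guideline Level-II regimen: Level-II match, nonconforming
        guide = TieredRecommendation.of({"TC+H"}, {"HP"})
        cat = classify_guideline_conformity(TieredRecommendation.of({"HP"}), guide)
        assert cat == C.LEVEL_II_MATCH and not is_conforming(cat)
        # outside every tier: not available
        guide2 = TieredRecommendation.of({"TC+H"}, {"EC"})
        assert classify_guideline_conformity(
            TieredRecommendation.of({"HP"}), guide2) == C.NOT_AVAILABLE
        # any Level-I intersection conforms, and takes precedence over Level II
        ai = TieredRecommendation.of({"TC+H", "HP"})
        assert classify_guideline_conformity(ai, guide) == C.LEVEL_I_MATCH

    def test_both_not_recommended_conforms(self):
        cat = classify_guideline_conformity(
            TieredRecommendation.not_recommended(), TieredRecommendation.not_recommended())
        assert cat == C.NOT_RECOMMENDED_MATCH and is_conforming(cat)


class TestIndicatorRate:
    @pytest.mark.parametrize(
        "num, den, rate",
        [(5107, 6372, 80.1), (6213, 6372, 97.5), (0, 10, 0.0), (1, 8, 12.5), (1, 16, 6.3)],
    )
    def test_rate_rounds_half_up_to_one_decimal(self, num, den, rate):
        flags = [True] * num + [False] * (den - num)
        assert indicator_rate(flags, lambda f: f)["Overall"].rate == rate

    def test_numerator_bounds_enforced(self):
        with pytest.raises(StudyValidationError):
            IndicatorResult(5, 4)
        with pytest.raises(StudyValidationError):
            IndicatorResult(0, 0)

    def test_empty_input_warns_not_divides(self):
        with pytest.warns(UserWarning):
            assert indicator_rate([], lambda f: f) == {}

    def test_group_counts_pool_to_overall(self):
        rng = np.random.default_rng(5)
        records = [(int(rng.integers(5)), bool(rng.random() < 0.7)) for _ in range(997)]
        table = indicator_rate(records, lambda r: r[1], grouping=lambda r: r[0])
        overall = table.pop("Overall")
        assert sum(t.numerator for t in table.values()) == overall.numerator
        assert sum(t.denominator for t in table.values()) == overall.denominator

    def test_strict_rule_never_beats_lenient_rule(self):
        rng = np.random.default_rng(11)
        labels = ["a", "b", "c", "d", "e"]
        pairs = []
        for _ in range(500):
            ref = (TieredRecommendation.of({labels[rng.integers(3)]}, {"d"})
                   if rng.random() < 0.8 else TieredRecommendation.not_recommended())
            phys = (Decision.recommend(labels[rng.integers(5)])
                    if rng.random() < 0.8 else Decision.not_recommended())
            pairs.append((phys, ref))
        cats = [classify_concordance(p, r) for p, r in pairs]
        strict = sum(map(is_concordant, cats))
        lenient = sum(c in (C.LEVEL_I_MATCH, C.LEVEL_II_MATCH, C.NOT_RECOMMENDED_MATCH)
                      for c in cats)
        assert strict <= lenient
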