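"""Inferential statistics: oracle equivalences and recovery simulations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cdsseval import (
    ContingencyTable,
    StudyValidationError,
    chi_square_test,
    logistic_risk_factors,
    mcnemar_test,
    propensity_match,
)
from cdsseval.stats import greedy_caliper_pairs

SENIORITY_REASON_COUNTS = [[296, 36, 81], [311, 47, 82], [255, 43, 114]]
HOSPITAL_REASON_COUNTS = [[299, 61, 103], [311, 29, 85], [252, 36, 89]]


class TestChiSquare:
    def test_seniority_reason_table(self):
        res = chi_square_test(np.array(SENIORITY_REASON_COUNTS))
        assert res.statistic == pytest.approx(13.888, abs=5e-4)
        assert res.df == 4
        assert res.p_value == pytest.approx(0.008, abs=5e-4)

    def test_hospital_reason_table(self):
        res = chi_square_test(np.array(HOSPITAL_REASON_COUNTS))
        assert res.statistic == pytest.approx(12.831, abs=5e-4)
        assert res.p_value == pytest.approx(0.012, abs=5e-4)

    def test_proportional_table_is_zero(self):
        assert chi_square_test([[10, 20], [30, 60]]).statistic == pytest.approx(0.0)

    def test_equals_brute_force_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t = rng.integers(1, 40, size=(rng.integers(2, 5), rng.integers(2, 5)))
            total = t.sum()
            expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
            brute = ((t - expected) ** 2 / expected).sum()
            assert chi_square_test(t).statistic == pytest.approx(brute)

    def test_zero_marginal_rejected(self):
        with pytest.raises(StudyValidationError, match="marginal"):
            chi_square_test([[0, 0], [3, 4]])

    def test_contingency_table_validation(self):
        with pytest.raises(StudyValidationError):
            ContingencyTable(np.array([[1, 2]]), ("r",), ("a", "b"))
        with pytest.raises(StudyValidationError):
            ContingencyTable(np.array([[1, -2], [3, 4]]), ("r", "s"), ("a", "b"))


def _exact_two_sided_oracle(b: int, n: int) -> float:
    """Enumerated two-sided binomial p at 1/2: sum of outcome probabilities
    no larger than the observed one."""
    probs = np.array([scipy.stats.binom.pmf(k, n, 0.5) for k in range(n + 1)])
    return float(probs[probs <= probs[b] * (1 + 1e-12)].sum())


class TestMcNemar:
    def test_symmetric_discordance_is_null(self):
        res = mcnemar_test(20, 20)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_closed_form_statistic(self):
        assert mcnemar_test(40, 10).statistic == pytest.approx(18.0)

    def test_small_sample_exact_branch(self):
        res = mcnemar_test(3, 0)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.25)

    def test_exact_branch_matches_full_enumeration(self):
        for n in range(1, 13):
            for b in range(n + 1):
                res = mcnemar_test(b, n - b)
                assert res.method == "exact"
                assert res.p_value == pytest.approx(_exact_two_sided_oracle(b, n), rel=1e-9)

    def test_agrees_with_statsmodels_large_sample(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        b, c = 40, 22
        ref = sm_mcnemar([[5, b], [c, 7]], exact=False, correction=False)
        res = mcnemar_test(b, c)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_no_discordant_pairs_warns(self):
        with pytest.warns(UserWarning):
            assert mcnemar_test(0, 0).p_value == 1.0


class TestLogisticRiskFactors:
    def test_recovers_known_log_odds(self):
        rng = np.random.default_rng(17)
        n = 5000
        stage = rng.choice(["I", "II", "III"], size=n, p=[0.36, 0.50, 0.14])
        beta = {"I": 0.0, "II": 0.3, "III": 0.8}
        logit = -0.5 + np.array([beta[s] for s in stage])
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        table = logistic_risk_factors(y.astype(int), pd.DataFrame({"tnm_stage": stage}))
        row = table[table["term"] == "tnm_stage_III"].iloc[0]
        assert abs(row["estimate"] - 0.8) < 3 * row["se"]

    def test_null_covariate_type_i_error_calibrated(self):
        rng = np.random.default_rng(23)
        rejections = 0
        reps = 300
        for _ in range(reps):
            x = rng.choice(["a", "b"], size=120)
            y = (rng.random(120) < 0.5).astype(int)
            try:
                table = logistic_risk_factors(y, pd.DataFrame({"x": x}))
            except StudyValidationError:  # rare degenerate draw
                continue
            rejections += int(table[table["term"] == "x_b"]["p_value"].iloc[0] < 0.05)
        assert 0.01 < rejections / reps < 0.10  # nominal 5%

    def test_constant_covariate_rejected(self):
        y = np.tile([0, 1], 25)
        with pytest.raises(StudyValidationError, match="constant"):
            logistic_risk_factors(y, pd.DataFrame({"x": ["a"] * 50}))

    def test_perfect_separation_is_diagnosed(self):
        y = np.array([0] * 25 + [1] * 25)
        x = np.array(["a"] * 25 + ["b"] * 25)
        with pytest.raises(StudyValidationError, match="separation"):
            logistic_risk_factors(y, pd.DataFrame({"x": x}))


class TestGreedyCaliperPairs:
    def test_within_caliper_pair_is_matched(self):
        assert greedy_caliper_pairs(np.array([0.500]), np.array([0.505]), 0.01) == [(0, 0)]

    def test_outside_caliper_left_unmatched(self):
        assert greedy_caliper_pairs(np.array([0.50]), np.array([0.52]), 0.01) == []

    def test_descending_traversal_and_nearest_choice(self):
        ps_a = np.array([0.30, 0.90])
        ps_b = np.array([0.895, 0.31, 0.905])
        pairs = greedy_caliper_pairs(ps_a, ps_b, 0.01)
        # the high-PS unit is matched first, to its nearest neighbour 0.895
        assert sorted(pairs) == [(0, 1), (1, 0)]

    def test_no_unit_reused_and_all_within_caliper(self):
        rng = np.random.default_rng(4)
        ps_a, ps_b = rng.random(60), rng.random(80)
        pairs = greedy_caliper_pairs(ps_a, ps_b, 0.01)
        used_a = [i for i, _ in pairs]
        used_b = [j for _, j in pairs]
        assert len(set(used_a)) == len(used_a) and len(set(used_b)) == len(used_b)
        assert all(abs(ps_a[i] - ps_b[j]) <= 0.01 + 1e-12 for i, j in pairs)

    def test_invariant_to_candidate_pool_permutation(self):
        rng = np.random.default_rng(12)
        ps_a, ps_b = rng.random(30), rng.random(40)
        perm = rng.permutation(40)
        pairs = greedy_caliper_pairs(ps_a, ps_b, 0.02)
        pairs_perm = greedy_caliper_pairs(ps_a, ps_b[perm], 0.02)
        matched = sorted((i, round(ps_b[j], 12)) for i, j in pairs)
        matched_perm = sorted((i, round(ps_b[perm][j], 12)) for i, j in pairs_perm)
        assert matched == matched_perm


def _smd(matched_a: pd.DataFrame, matched_b: pd.DataFrame) -> pd.Series:
    da = pd.get_dummies(matched_a, dtype=float)
    db = pd.get_dummies(matched_b, dtype=float).reindex(columns=da.columns, fill_value=0.0)
    pooled_sd = np.sqrt((da.var(ddof=1) + db.var(ddof=1)) / 2)
    return ((da.mean() - db.mean()).abs() / pooled_sd.replace(0, np.nan)).fillna(0.0)


class TestPropensityMatch:
    def test_identical_distributions_match_and_balance(self):
        rng = np.random.default_rng(31)

        def draw(n):
            return pd.DataFrame({
                "age": rng.choice(["<=44", "45-54", ">=55"], size=n, p=[0.27, 0.48, 0.25]),
                "tnm": rng.choice(["I", "II", "III"], size=n, p=[0.36, 0.50, 0.14]),
                "subtype": rng.choice(list("abcde"), size=n),
                "stage": rng.choice(["t", "c", "r", "e"], size=n),
            })

        a, b = draw(200), draw(200)
        result = propensity_match(a, b, caliper=0.01, seed=0)
        assert result.n_pairs >= 0.9 * 200
        ia = [i for i, _ in result.pairs]
        ib = [j for _, j in result.pairs]
        assert (_smd(a.iloc[ia], b.iloc[ib]) < 0.1).all()
        frame = result.to_frame()
        assert (frame["abs_delta_ps"] <= 0.01 + 1e-12).all()

    def test_empty_side_warns(self):
        with pytest.warns(UserWarning):
            res = propensity_match(pd.DataFrame({"x": []}), pd.DataFrame({"x": ["a"]}))
        assert res.n_pairs == 0

    def test_mismatched_columns_rejected(self):
        with pytest.raises(StudyValidationError):
            propensity_match(pd.DataFrame({"x": ["a", "b"]}), pd.DataFrame({"y": ["a", "b"]}))

    def test_bad_caliper_rejected(self):
        with pytest.raises(StudyValidationError):
            propensity_match(pd.DataFrame({"x": ["a"]}), pd.DataFrame({"x": ["a"]}), caliper=0.0)
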