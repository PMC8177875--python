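"""Permutation tests, FDR, correlations, lateralization index."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from alpharatio.exceptions import InvalidArgumentError, UndefinedStatisticError
from alpharatio.groupstats import (
    FeatureMatrix,
    GroupContrast,
    fdr_correct,
    group_compare,
    lateralization_index,
    lateralization_table,
    pearson_correlation,
    permutation_ttest,
)


def brute_force_perm_p(a, b):
    """Independent enumeration oracle: pooled-variance t over all label splits."""
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    t_obs = scipy.stats.ttest_ind(a, b, equal_var=True).statistic
    count = 0
    total = 0
    for idx in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        t = scipy.stats.ttest_ind(pooled[mask], pooled[~mask], equal_var=True).statistic
        total += 1
        if abs(t) >= abs(t_obs) - 1e-10:
            count += 1
    return t_obs, count / total


class TestPermutationTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        res = permutation_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_perm=100, seed=0)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0
        assert res.exhaustive  # C(6,3) = 20 <= 100

    def test_exhaustive_matches_enumeration_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t_ref, p_ref = brute_force_perm_p(a, b)
        res = permutation_ttest(a, b, n_perm=1000, seed=0)
        assert res.exhaustive and res.n_permutations == comb(6, 3)
        assert res.t == pytest.approx(t_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, abs=0)

    def test_matches_scipy_exact_permutation_test(self):
        a, b = np.array([1.0, 2.0, 3.0, 4.0]), np.array([5.0, 6.0, 7.0])
        ours = permutation_ttest(a, b, n_perm=100, seed=0)

        def stat(x, y):
            return scipy.stats.ttest_ind(x, y, equal_var=True).statistic

        ref = scipy.stats.permutation_test(
            (a, b), stat, permutation_type="independent", alternative="two-sided",
            n_resamples=np.inf,
        )
        assert ours.p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_sampled_p_converges_to_exact(self, rng):
        a = rng.standard_normal(5) + 1.2
        b = rng.standard_normal(5)
        exact = permutation_ttest(a, b, n_perm=300, seed=0)  # C(10,5)=252 exhaustive
        assert exact.exhaustive
        p_exact = exact.p
        n_perm = 200  # below the 252 distinct splits, so sampling is exercised
        band = 3 * np.sqrt(p_exact * (1 - p_exact) / n_perm)
        hits = 0
        for seed in range(20):
            sampled = permutation_ttest(a, b, n_perm=n_perm, seed=seed)
            assert not sampled.exhaustive
            hits += abs(sampled.p - p_exact) < band + 1 / (n_perm + 1)
        assert hits >= 19

    def test_sampled_p_strictly_positive_with_add_one(self, rng):
        a = rng.standard_normal(8) + 50.0  # overwhelming separation
        b = rng.standard_normal(8)
        res = permutation_ttest(a, b, n_perm=999, seed=1)
        assert res.p >= 1.0 / (999 + 1)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            permutation_ttest([1.0, 1.0, 1.0], [1.0, 1.0], n_perm=10)

    def test_group_size_and_n_perm_contracts(self):
        with pytest.raises(InvalidArgumentError):
            permutation_ttest([1.0], [2.0, 3.0], n_perm=10)
        with pytest.raises(InvalidArgumentError):
            permutation_ttest([1.0, 2.0], [2.0, 3.0], n_perm=0)

    def test_null_rejection_rate_calibrated(self, rng):
        # statistics-level check; the cohort-level version runs in acceptance
        rej = 0
        reps = 1000
        for i in range(reps):
            a = rng.standard_normal(6)
            b = rng.standard_normal(6)
            rej += permutation_ttest(a, b, n_perm=199, seed=i).p <= 0.05
        assert 0.032 <= rej / reps <= 0.071


class TestFDR:
    def test_bh_stepup_hand_case_all_rejected(self):
        # sorted p_i <= i * 0.05 / 4 for every i, so BH rejects all four
        q, rej = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]), level=0.05)
        assert rej.all()
        assert np.all(q <= 0.05)

    def test_large_ps_not_rejected(self):
        _, rej = fdr_correct(np.array([0.2, 0.5]), level=0.05)
        assert not rej.any()

    def test_equal_ps_all_or_nothing(self):
        q, rej = fdr_correct(np.full(100, 0.01), level=0.05)
        assert rej.all()
        np.testing.assert_allclose(q, 0.01)

    def test_order_invariance(self, rng):
        p = rng.uniform(0.001, 1.0, 50)
        q1, r1 = fdr_correct(p)
        perm = rng.permutation(50)
        q2, r2 = fdr_correct(p[perm])
        np.testing.assert_allclose(q2, q1[perm])
        np.testing.assert_array_equal(r2, r1[perm])

    def test_matches_manual_step_up(self, rng):
        p = rng.uniform(0.0001, 1.0, 30)
        _, rej = fdr_correct(p, level=0.05)
        order = np.argsort(p)
        below = p[order] <= (np.arange(1, 31) * 0.05 / 30)
        k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
        expected = np.zeros(30, dtype=bool)
        expected[order[:k]] = True
        np.testing.assert_array_equal(rej, expected)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5, np.nan])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(InvalidArgumentError):
            fdr_correct(np.array([0.5, bad]))


class TestGroupCompare:
    def _fm(self, values, groups, feature_names=None):
        n, n_sig, n_feat = values.shape
        feature_names = feature_names or [f"f{j}" for j in range(n_feat)]
        return FeatureMatrix(
            values=values,
            feature_names=feature_names,
            subject_table=pd.DataFrame(
                {"subject_id": [f"s{i}" for i in range(n)], "group": groups}
            ),
            signal_meta=pd.DataFrame({"name": [f"sig{k}" for k in range(n_sig)]}),
        )

    def test_single_signal_reduces_to_permutation_ttest(self, rng):
        values = rng.standard_normal((10, 1, 3))
        groups = ["a"] * 5 + ["b"] * 5
        fm = self._fm(values, groups)
        res = group_compare(fm, n_permutations=400, seed=7, groups=("a", "b"))
        direct = permutation_ttest(values[:5, 0, :], values[5:, 0, :], n_perm=400, seed=7)
        np.testing.assert_allclose(res.p_perm.to_numpy().ravel(), np.asarray(direct.p))
        np.testing.assert_allclose(res.t_obs.to_numpy().ravel(), np.asarray(direct.t))

    def test_shared_schedule_matches_flat_call(self, rng):
        values = rng.standard_normal((12, 4, 2))
        groups = ["a"] * 6 + ["b"] * 6
        fm = self._fm(values, groups)
        res = group_compare(fm, n_permutations=500, seed=3, groups=("a", "b"))
        flat = permutation_ttest(
            values[:6].reshape(6, -1), values[6:].reshape(6, -1), n_perm=500, seed=3
        )
        np.testing.assert_allclose(res.p_perm.to_numpy().ravel(), np.asarray(flat.p))

    def test_known_effect_detected_null_features_spared(self, rng):
        values = rng.standard_normal((24, 6, 2))
        values[12:, :3, 0] += 2.5  # effect in feature 0, signals 0-2
        fm = self._fm(values, ["a"] * 12 + ["b"] * 12)
        res = group_compare(fm, n_permutations=999, seed=1, groups=("b", "a"))
        assert res.rejected.iloc[:3, 0].all()
        assert res.rejected.iloc[:, 1].sum() <= 1

    def test_results_object_summary_and_frame(self, rng):
        values = rng.standard_normal((10, 2, 2))
        fm = self._fm(values, ["a"] * 5 + ["b"] * 5)
        model = GroupContrast(fm, n_permutations=200, groups=("a", "b"))
        res = model.fit(seed=0)
        frame = res.to_frame()
        assert set(frame.columns) == {"signal_id", "feature", "t", "p", "q", "rejected"}
        assert len(frame) == 4
        text = res.summary()
        assert "Permutation group contrast" in text and "a - b" in text

    def test_requires_exactly_two_groups(self, rng):
        fm = self._fm(rng.standard_normal((6, 1, 1)), ["a", "a", "b", "b", "c", "c"])
        with pytest.raises(InvalidArgumentError):
            group_compare(fm, n_permutations=10)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, -1.0, 0.0, 1.0])
        res = pearson_correlation(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_five_point_set_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        xm, ym = x - x.mean(), y - y.mean()
        r_hand = float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
        t_hand = r_hand * np.sqrt(3 / (1 - r_hand**2))
        p_hand = 2 * scipy.stats.t.sf(abs(t_hand), df=3)
        res = pearson_correlation(x, y)
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        assert res.p == pytest.approx(p_hand, rel=1e-9)

    def test_missing_pairs_dropped_not_imputed(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.1, 2.2, 3.0, np.nan, 5.1])
        res = pearson_correlation(x, y)
        assert res.n == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLateralization:
    def test_formula_cases(self):
        assert lateralization_index(3.0, 1.0) == pytest.approx(0.5)
        assert lateralization_index(2.0, 2.0) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        left=st.floats(0.01, 100.0, allow_nan=False),
        right=st.floats(0.01, 100.0, allow_nan=False),
    )
    def test_antisymmetric_and_bounded(self, left, right):
        li = lateralization_index(left, right)
        assert li == pytest.approx(-lateralization_index(right, left))
        assert -1.0 < li < 1.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            lateralization_index(0.0, 1.0)

    def test_table_uses_homologous_pairs(self):
        values = np.array([[[1.0], [1.0], [2.0]], [[1.5], [0.5], [2.0]]])
        fm = FeatureMatrix(
            values=values,
            feature_names=["alpha_power_ratio"],
            subject_table=pd.DataFrame({"subject_id": ["a", "b"], "group": ["control", "patient"]}),
            signal_meta=pd.DataFrame(
                {
                    "name": ["r1_L", "r1_R", "mid"],
                    "hemisphere": ["L", "R", "midline"],
                    "pair": [0, 0, -1],
                }
            ),
        )
        table = lateralization_table(fm)
        assert len(table) == 2  # one pair, two subjects; the midline signal is skipped
        assert table.loc[table["subject_id"] == "a", "li"].iloc[0] == 0.0
        assert table.loc[table["subject_id"] == "b", "li"].iloc[0] == pytest.approx(0.5)
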