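import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from wmpipeline.grids import VolumeGrid
from wmpipeline.stats import (
    AncovaResult,
    DegenerateInputError,
    EmptyMaskError,
    ancova_trend,
    chi_square_incidence,
    cohen_d_pooled,
    flag_outliers,
    logistic_univariate,
    masked_mean,
    nested_f,
    paired_t,
    roc_discrimination,
)


class TestMaskedMean:
    def test_constant_map(self):
        vol = VolumeGrid(np.full((3, 3, 3), 4.5), (2, 2, 2))
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[2, 2, 2] = True
        s = masked_mean(vol, mask)
        assert s.mean == 4.5 and s.voxel_count == 2

    def test_two_voxel_example(self):
        vol = VolumeGrid(np.array([1.0, 3.0]).reshape(2, 1, 1), (2, 2, 2))
        s = masked_mean(vol, np.ones((2, 1, 1), bool))
        assert s.mean == 2.0

    def test_empty_mask_raises(self):
        vol = VolumeGrid(np.zeros((2, 2, 2)), (2, 2, 2))
        with pytest.raises(EmptyMaskError):
            masked_mean(vol, np.zeros((2, 2, 2), bool))


class TestPairedT:
    def test_identical_series(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed(self):
        # differences {1,2,3}: mean 2, sd 1 -> t = 2/(1/sqrt(3)) = 3.4641, df 2
        t, df, p = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert df == 2
        assert t == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(2 * np.sqrt(3), 2), abs=1e-12)

    def test_zero_variance_nonzero_mean(self):
        with pytest.raises(DegenerateInputError):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_missing_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


class TestCohenD:
    @pytest.mark.parametrize(
        "m1,s1,m2,s2,expected",
        [
            (0.338, 0.024, 0.299, 0.042, 1.13),
            (0.692, 0.034, 0.833, 0.061, -2.85),
            (56.80, 0.99, 54.37, 1.51, 1.91),
            (1.002, 0.092, 1.086, 0.117, -0.80),
        ],
    )
    def test_published_effect_sizes(self, m1, s1, m2, s2, expected):
        assert cohen_d_pooled(m1, s1, m2, s2) == pytest.approx(expected, abs=0.02)

    def test_equal_means(self):
        assert cohen_d_pooled(1.0, 0.5, 1.0, 0.2) == 0.0

    def test_both_sds_zero(self):
        with pytest.raises(DegenerateInputError):
            cohen_d_pooled(1.0, 0.0, 2.0, 0.0)


def _brute_force_auc(pos, neg):
    wins = ties = 0
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = roc_discrimination([0.6, 0.7, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.threshold == pytest.approx(0.75)
        assert r.sensitivity == r.specificity == r.accuracy == 1.0
        assert r.direction == "high"

    def test_identical_distributions(self):
        r = roc_discrimination([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(0.5)

    def test_direction_low(self):
        r = roc_discrimination([0.9, 0.8, 0.7, 0.6], [0, 0, 1, 1])
        assert r.direction == "low"
        assert r.auc == 1.0

    @settings(max_examples=100, deadline=None)
    @given(
        pos=st.lists(st.integers(0, 8), min_size=1, max_size=12),
        neg=st.lists(st.integers(0, 8), min_size=1, max_size=12),
    )
    def test_auc_equals_pair_counting_oracle(self, pos, neg):
        values = np.array(pos + neg, dtype=float)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        if np.unique(values).size < 2:
            return
        r = roc_discrimination(values, labels)
        oracle = _brute_force_auc(pos, neg)
        oracle = max(oracle, 1 - oracle)  # orientation-free
        assert r.auc == pytest.approx(oracle, abs=1e-12)

    def test_ci_contains_point_estimate(self, rng):
        values = rng.normal(size=200)
        labels = (rng.random(200) < 0.5).astype(int)
        if labels.sum() in (0, 200):
            labels[0] = 1 - labels[0]
        r = roc_discrimination(values, labels)
        assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]

    def test_delong_coverage(self):
        """95% CI coverage over replicates, checked at a 0.01-level binomial bound."""
        true_auc = sps.norm.cdf(1.0 / np.sqrt(2.0))  # shift-1, unit-variance classes
        hits = 0
        reps = 400
        rng = np.random.default_rng(99)
        for _ in range(reps):
            neg = rng.normal(0, 1, 60)
            pos = rng.normal(1, 1, 60)
            r = roc_discrimination(np.concatenate([neg, pos]),
                                   np.concatenate([np.zeros(60), np.ones(60)]))
            hits += r.auc_ci[0] <= true_auc <= r.auc_ci[1]
        # binomial(400, .95): 0.005/0.995 quantiles ~ 368..391
        assert sps.binom.ppf(0.005, reps, 0.95) <= hits <= sps.binom.ppf(0.995, reps, 0.95)

    def test_one_class_missing(self):
        with pytest.raises(ValueError):
            roc_discrimination([1.0, 2.0], [1, 1])


class TestLogistic:
    def test_slope_recovers_analytic_logit(self):
        rng = np.random.default_rng(5)
        n = 20000
        x = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        p = np.where(x > 0, 0.75, 0.25)
        y = (rng.random(n) < p).astype(int)
        intercept, slope, _, separated = logistic_univariate(x, y)
        true_slope = np.log(0.75 / 0.25)  # eta = 0 + logit(0.75) * x
        se = 3.0 / np.sqrt(n)  # generous 3-SE scale bound
        assert not separated
        assert abs(slope - true_slope) < 3 * se + 0.05
        assert abs(intercept) < 0.1

    def test_null_slope(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=5000)
        y = (rng.random(5000) < 0.5).astype(int)
        _, slope, _, separated = logistic_univariate(x, y)
        assert abs(slope) < 0.1 and not separated

    def test_separation_flag(self):
        _, _, _, separated = logistic_univariate([0.0, 1.0, 10.0, 11.0], [0, 0, 1, 1])
        assert separated

    def test_constant_values(self):
        with pytest.raises(DegenerateInputError):
            logistic_univariate([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])


class TestAncova:
    def test_hand_computed_one_way(self):
        # groups {1,2,3} and {3,4,5}: SSB 6 (df 1), SSW 4 (df 4) -> F 6.0
        outcome = [1, 2, 3, 3, 4, 5]
        score = [0, 0, 0, 1, 1, 1]
        res = ancova_trend(outcome, score)
        f, p = res.terms["score"]
        assert f == pytest.approx(6.0, abs=1e-10)
        assert p == pytest.approx(sps.f.sf(6.0, 1, 4), abs=1e-10)

    def test_null_f_near_one(self, rng):
        outcome = rng.normal(size=3000)
        score = rng.integers(0, 4, size=3000)
        res = ancova_trend(outcome, score)
        f, p = res.terms["score"]
        assert 0.0 <= f < 4.0 and p > 0.001

    def test_constant_covariates_reduce_to_anova(self):
        outcome = [1.0, 2.0, 3.0, 3.0, 4.0, 5.0]
        score = [0, 0, 0, 1, 1, 1]
        with pytest.warns(UserWarning):
            res = ancova_trend(outcome, score, age=[50.0] * 6, gender=["M"] * 6)
        assert res.terms["score"][0] == pytest.approx(6.0, abs=1e-10)

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            ancova_trend([1.0, 2.0], [0, 0])

    def test_result_invariants(self):
        with pytest.raises(ValueError):
            AncovaResult(terms={"score": (-1.0, 0.5)}, r_squared=0.5, df_resid=10)


class TestNestedF:
    @staticmethod
    def _ols(y, X):
        import statsmodels.api as sm

        return sm.OLS(y, sm.add_constant(X)).fit()

    def test_duplicated_column_gives_zero_f(self, rng):
        x = rng.normal(size=50)
        y = 2 * x + rng.normal(size=50)
        small = self._ols(y, x)
        big = self._ols(y, np.column_stack([x, x]))
        f, df1, df2, p = nested_f(small, big)
        assert f == 0.0 and df1 == 0 and p == 1.0

    def test_textbook_two_predictor(self, rng):
        # hand formula: F = ((RSS_s - RSS_b)/d) / (RSS_b/df_b)
        x1 = rng.normal(size=40)
        x2 = rng.normal(size=40)
        y = 1 + x1 + 0.5 * x2 + rng.normal(size=40)
        small = self._ols(y, x1)
        big = self._ols(y, np.column_stack([x1, x2]))
        f, df1, df2, p = nested_f(small, big)
        expected = ((small.ssr - big.ssr) / 1) / (big.ssr / big.df_resid)
        assert f == pytest.approx(expected, rel=1e-12)
        assert df1 == 1 and df2 == big.df_resid

    def test_non_nested_rejected(self, rng):
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        y = rng.normal(size=30)
        with pytest.raises(ValueError):
            nested_f(self._ols(y, x1), self._ols(y, x2))

    def test_null_block_follows_f_distribution(self):
        """KS test of the nested-F statistic against F(df1, df2) under the null."""
        rng = np.random.default_rng(17)
        n, k = 60, 3
        stats = []
        df1 = df2 = None
        for _ in range(300):
            x = rng.normal(size=n)
            y = 1 + x + rng.normal(size=n)
            block = rng.normal(size=(n, k))  # pure noise block
            small = self._ols(y, x)
            big = self._ols(y, np.column_stack([x, block]))
            f, df1, df2, _ = nested_f(small, big)
            stats.append(f)
        _, p = sps.kstest(stats, "f", args=(df1, df2))
        assert p > 0.01


class TestChiSquare:
    def test_hand_computed(self):
        chi2, df, p = chi_square_incidence([[10, 20], [20, 10]])
        assert chi2 == pytest.approx(20.0 / 3.0, abs=1e-12)
        assert df == 1

    def test_proportional_margins_zero(self):
        chi2, _, p = chi_square_incidence([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_ex_smoker_incidence_significant(self):
        # reconstructed male/female ex-smoker counts: 50.8% of 358, 38.7% of 318
        male_yes = round(0.508 * 358)
        female_yes = round(0.387 * 318)
        chi2, df, p = chi_square_incidence(
            [[male_yes, 358 - male_yes], [female_yes, 318 - female_yes]]
        )
        assert p < 0.01

    def test_zero_marginal(self):
        with pytest.raises(ValueError):
            chi_square_incidence([[0, 0], [5, 5]])


class TestOutliers:
    def _frame(self, values, biomarker="MD"):
        return pd.DataFrame({
            "subject": [f"s{i}" for i in range(len(values))],
            "biomarker": biomarker,
            "mean": values,
        })

    def test_all_equal_nothing_flagged(self):
        with pytest.warns(UserWarning):
            out = flag_outliers(self._frame([1.0] * 12))
        assert not out["flagged"].any()

    def test_single_gross_outlier(self):
        values = [1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 0.98, 1.01, 0.99, 1.0, 5.0]
        out = flag_outliers(self._frame(values))
        assert out["flagged"].sum() == 1
        assert out.loc[out["flagged"], "mean"].iloc[0] == 5.0

    def test_contaminated_fraction_recovered(self):
        rng = np.random.default_rng(3)
        n = 4000
        x = rng.normal(0, 1, n)
        contaminated = rng.random(n) < 0.05
        x[contaminated] += 6.0 * np.sign(rng.random(contaminated.sum()) - 0.5)
        out = flag_outliers(self._frame(x), z_cut=3.5)
        frac = out["flagged"].mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 3 * se + 0.01

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            flag_outliers(self._frame([1.0] * 5))
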