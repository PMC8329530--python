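"""Cohort statistics: rank tests against enumeration oracles, regressions,
and logistic outcome models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from ctedema import (CohortSpec, OutcomeModel, compare_models_aic,
                     fit_outcome_model, generate_cohort, mann_whitney,
                     paired_wilcoxon, summarize_cohort, univariable_linear)
from ctedema.errors import DegenerateInputError, SeparationError


# ---------------------------------------------------------------------------
# independent enumeration oracles
# ---------------------------------------------------------------------------

def wilcoxon_exact_bruteforce(x, y):
    """Two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(y, float) - np.asarray(x, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    pats = np.array(list(itertools.product([0, 1], repeat=len(d))))
    w = pats @ ranks
    p_le = np.mean(w <= obs + 1e-9)
    p_ge = np.mean(w >= obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


def mannwhitney_exact_bruteforce(a, b):
    """Two-sided U-test p by enumerating all group labelings."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    obs = sum(x > y for x in a for y in b)
    us = []
    for comb in itertools.combinations(range(len(pooled)), len(a)):
        aa = pooled[list(comb)]
        bb = np.delete(pooled, list(comb))
        us.append(sum(x > y for x in aa for y in bb))
    us = np.asarray(us, float)
    p_le = np.mean(us <= obs + 1e-9)
    p_ge = np.mean(us >= obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestPairedWilcoxon:
    def test_six_positive_pairs_exact_p(self):
        t = paired_wilcoxon(np.zeros(6), np.arange(1.0, 7.0))
        assert t.p_value == pytest.approx(2 / 2 ** 6, abs=1e-15)
        assert t.exact

    def test_antisymmetric_differences_null_center(self):
        x = np.zeros(8)
        y = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0])
        t = paired_wilcoxon(x, y)
        assert t.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        x = rng.normal(0, 1, n)
        y = x + rng.normal(1.0, 0.5, n)
        t = paired_wilcoxon(x, y)
        assert t.p_value == pytest.approx(wilcoxon_exact_bruteforce(x, y),
                                          abs=1e-12)

    def test_zero_differences_dropped_and_counted(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 2.0, 4.0, 5.0, 6.0, 7.0])
        t = paired_wilcoxon(x, y)
        assert t.n_zeros_dropped == 2
        assert t.n == (4,)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_wilcoxon([1.0, 2.0], [1.0, 2.0])

    def test_large_n_approximation_close_to_exact(self):
        # n just beyond the exact cutoff: approx and DP-exact should agree well
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0.3, 1.0, 40)
        approx = paired_wilcoxon(x, y, exact_max_n=25)
        exact = paired_wilcoxon(x, y, exact_max_n=40)
        assert not approx.exact and exact.exact
        assert approx.p_value == pytest.approx(exact.p_value, rel=0.15)


class TestMannWhitney:
    def test_fully_separated_groups(self):
        t = mann_whitney([1, 2, 3], [4, 5, 6])
        assert t.statistic == 0.0
        assert t.p_value == pytest.approx(0.1, abs=1e-15)
        assert t.exact

    def test_identical_samples_p_one(self):
        t = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        na, nb = rng.integers(3, 9, 2)
        a = rng.normal(0, 1, na)
        b = rng.normal(0.8, 1, nb)
        t = mann_whitney(a, b)
        assert t.p_value == pytest.approx(mannwhitney_exact_bruteforce(a, b),
                                          abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            mann_whitney([], [1.0])


class TestUnivariableLinear:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        r = univariable_linear(x, 2.0 * x)
        assert r.beta == pytest.approx(2.0, abs=1e-10)
        assert r.ci_high - r.ci_low == pytest.approx(0.0, abs=1e-8)

    def test_independent_data_ci_contains_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 2000)
        y = rng.normal(0, 1, 2000)
        r = univariable_linear(x, y)
        assert r.ci_low <= 0.0 <= r.ci_high

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            univariable_linear(np.ones(10), np.arange(10.0))

    def test_slope_ci_coverage(self):
        """95% CI covers the true slope 0.37 in >= 90 of 100 replicates."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(10, 4, 500)
            y = 0.37 * x + rng.normal(0, 2, 500)
            r = univariable_linear(x, y)
            hits += r.ci_low <= 0.37 <= r.ci_high
        assert hits >= 90


class TestOutcomeModel:
    @staticmethod
    def _binary_cohort(seed=0, n=200):
        rng = np.random.default_rng(seed)
        x = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        p = np.where(x == 1, 0.3, 0.6)
        fav = rng.random(n) < p
        return pd.DataFrame({"d_ev": x * 10.0,
                             "mrs_90d": np.where(fav, 1.0, 5.0)}), x, fav

    def test_binary_predictor_or_equals_cross_product_ratio(self):
        df, x, fav = self._binary_cohort()
        m = fit_outcome_model(df, "d_ev", [], per_ml=10.0)
        a = np.sum((x == 1) & fav)
        b = np.sum((x == 1) & ~fav)
        c = np.sum((x == 0) & fav)
        d = np.sum((x == 0) & ~fav)
        assert m.terms[0][1] == pytest.approx(a * d / (b * c), rel=1e-8)

    def test_or_scaling_consistency(self):
        """beta(per 10 ml) = 10 x beta(per 1 ml); OR = exp(beta)."""
        df, _ = generate_cohort(CohortSpec(n_patients=400, seed=3))
        m1 = fit_outcome_model(df, "d_ev", [], per_ml=1.0)
        m10 = fit_outcome_model(df, "d_ev", [], per_ml=10.0)
        b1 = np.log(m1.terms[0][1])
        b10 = np.log(m10.terms[0][1])
        assert b10 == pytest.approx(10.0 * b1, rel=1e-6)

    def test_aic_against_hand_computed_loglikelihood(self):
        # tiny table where the log-likelihood is recomputed from first principles
        df = pd.DataFrame({"d_ev": [0.0, 5.0, 10.0, 15.0, 20.0, 25.0],
                           "mrs_90d": [1.0, 1.0, 5.0, 1.0, 5.0, 5.0]})
        m = fit_outcome_model(df, "d_ev", [], per_ml=10.0)
        yv = (df["mrs_90d"] <= 2).to_numpy(float)
        xv = df["d_ev"].to_numpy() / 10.0
        eta = m.params["const"] + m.params["d_ev_per10ml"] * xv
        p = 1.0 / (1.0 + np.exp(-eta))
        ll = np.sum(yv * np.log(p) + (1 - yv) * np.log(1 - p))
        assert m.loglik == pytest.approx(ll, abs=1e-8)
        assert m.aic == pytest.approx(-2 * ll + 2 * 2, abs=1e-8)

    def test_noise_confounder_raises_aic_in_median(self):
        deltas = []
        for seed in range(20):
            df, _ = generate_cohort(CohortSpec(n_patients=300, seed=seed))
            rng = np.random.default_rng(1000 + seed)
            df["noise"] = rng.normal(0, 1, len(df))
            m0 = fit_outcome_model(df, "d_ev", [])
            m1 = fit_outcome_model(df, "d_ev", ["noise"])
            deltas.append(m1.aic - m0.aic)
        assert np.median(deltas) > 0

    def test_constant_progression_rejected(self):
        df = pd.DataFrame({"d_ev": np.zeros(20),
                           "mrs_90d": [1.0, 5.0] * 10})
        with pytest.raises(ValueError, match="constant"):
            fit_outcome_model(df, "d_ev", [])

    def test_degenerate_outcome_rejected(self):
        df = pd.DataFrame({"d_ev": np.arange(20.0), "mrs_90d": np.ones(20)})
        with pytest.raises(DegenerateInputError):
            fit_outcome_model(df, "d_ev", [])

    def test_separation_detected(self):
        df = pd.DataFrame({"d_ev": np.r_[np.zeros(10), np.ones(10) * 30],
                           "mrs_90d": np.r_[np.ones(10), np.full(10, 5.0)]})
        with pytest.raises(SeparationError):
            fit_outcome_model(df, "d_ev", [])

    def test_complete_case_n(self):
        df, _ = generate_cohort(CohortSpec(n_patients=300, seed=4,
                                           mrs_missing_rate=0.1))
        m = fit_outcome_model(df, "d_ev", ["age"])
        assert m.n == int(df[["d_ev", "age", "mrs_90d"]].dropna().shape[0])

    def test_compare_models(self):
        df, _ = generate_cohort(CohortSpec(n_patients=300, seed=5))
        m1 = fit_outcome_model(df, "d_ev", ["age"])
        m2 = fit_outcome_model(df, "d_eciv", ["age"])
        cmp = compare_models_aic(m1, m2)
        assert cmp["delta_aic"] == pytest.approx(m1.aic - m2.aic)
        assert compare_models_aic(m1, m1)["delta_aic"] == 0.0

    def test_compare_models_different_n_rejected(self):
        m1 = OutcomeModel(terms=[], aic=10.0, n=100)
        m2 = OutcomeModel(terms=[], aic=12.0, n=99)
        with pytest.raises(ValueError, match="different n"):
            compare_models_aic(m1, m2)


class TestSummarizeCohort:
    def test_median_and_iqr_definition(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0, 5.0]})
        s = summarize_cohort(df, continuous=["v"])
        row = s.iloc[0]
        assert (row["median"], row["q1"], row["q3"]) == (3.0, 2.0, 4.0)

    def test_single_record_degenerate_iqr(self):
        df = pd.DataFrame({"v": [7.0]})
        row = summarize_cohort(df, continuous=["v"]).iloc[0]
        assert row["median"] == row["q1"] == row["q3"] == 7.0

    def test_missing_counts_reported(self):
        df = pd.DataFrame({"v": [1.0, np.nan, 3.0], "g": ["a", "b", None]})
        s = summarize_cohort(df, continuous=["v"], categorical=["g"])
        assert int(s.loc[s.variable == "v", "n_missing"].iloc[0]) == 1
        assert int(s.loc[s.variable == "g", "n_missing"].iloc[0]) == 1
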