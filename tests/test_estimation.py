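from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.special import expit

from itcmed.cohort import simulate_choices
from itcmed.design import TrialDesign, design_to_frame
from itcmed.estimation import (CannotImputeError, DegenerateTrialError,
                               InconsistentPatternError, InvalidTrialError,
                               NonIdentifiableError, classify_pattern,
                               estimate_participants, estimate_sensitivity,
                               fit_indifference_point, impute_log_k,
                               indifference_k, log_k_to_k,
                               remove_extreme_outliers)


def _bisection_indifference_k(a1, d1, a2, d2):
    """Independent root of A1/(1+k*D1) = A2/(1+k*D2)."""
    f = lambda k: a1 / (1 + k * d1) - a2 / (1 + k * d2)
    return brentq(f, 1e-12, 1e6, xtol=1e-300, rtol=1e-15)


class TestIndifferenceK:
    def test_immediate_ss_example(self):
        t = TrialDesign(8, 0, 10, 14)
        assert indifference_k(t) == pytest.approx(2 / 112, abs=1e-12)
        assert indifference_k(t) == pytest.approx(
            _bisection_indifference_k(8, 0, 10, 14), rel=1e-10)

    def test_zero_denominator_is_degenerate(self):
        with pytest.raises(DegenerateTrialError):
            indifference_k(TrialDesign(10, 14, 20, 28))  # 10*28 - 20*14 = 0

    def test_ll_not_larger_raises(self):
        bad = SimpleNamespace(ss_amount=10, ss_delay=0, ll_amount=10, ll_delay=14)
        with pytest.raises(InvalidTrialError):
            indifference_k(bad)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a1=st.floats(1, 50), ratio=st.floats(1.05, 10),
           d1=st.floats(0, 30), d_gap=st.floats(1, 40))
    def test_formula_matches_bisection_root(self, a1, ratio, d1, d_gap):
        a2, d2 = a1 * ratio, d1 + d_gap
        if a1 * d2 - a2 * d1 < 1e-6 * a2 * max(d2, 1.0):
            return  # (near-)degenerate trial: no positive root to compare
        t = TrialDesign(a1, d1, a2, d2)
        assert indifference_k(t) == pytest.approx(
            _bisection_indifference_k(a1, d1, a2, d2), rel=1e-10)


class TestIndifferencePointFit:
    def test_log_k_is_minus_alpha_over_beta(self, indifference_ks):
        rng = np.random.default_rng(3)
        x = np.log(indifference_ks)
        y = (rng.random(len(x)) < expit(4 + 2 * x)).astype(float)
        est = fit_indifference_point(y, indifference_ks)
        assert est.log_k == pytest.approx(-est.alpha / est.beta)

    def test_large_sample_recovers_50pct_point(self):
        # choices generated from P(LL) = logistic(4 + 2*log k) -> 50% at -2
        rng = np.random.default_rng(0)
        ks = np.exp(rng.uniform(-5, 1, 2000))
        y = (rng.random(2000) < expit(4 + 2 * np.log(ks))).astype(float)
        est = fit_indifference_point(y, ks)
        assert est.converged and est.beta > 0
        assert est.log_k == pytest.approx(-2.0, abs=0.1)

    def test_noiseless_chooser_recovered_within_grid_gap(self, indifference_ks):
        x = np.sort(np.log(indifference_ks))
        y = (np.log(indifference_ks) > -2.0).astype(float)
        est = fit_indifference_point(y, indifference_ks)
        assert est.separated
        assert abs(est.log_k - (-2.0)) <= np.diff(x).max() / 2

    def test_trial_order_irrelevant(self, indifference_ks):
        rng = np.random.default_rng(5)
        y = (np.log(indifference_ks) > -1.5).astype(float)
        perm = rng.permutation(len(y))
        a = fit_indifference_point(y, indifference_ks)
        b = fit_indifference_point(y[perm], indifference_ks[perm])
        assert a.log_k == pytest.approx(b.log_k, abs=1e-9)

    def test_degenerate_inputs_raise(self, indifference_ks):
        with pytest.raises(NonIdentifiableError):
            fit_indifference_point(np.zeros(32), indifference_ks)
        with pytest.raises(InconsistentPatternError):
            # LL only at the *lowest* indifference k: reversed preference
            y = (np.log(indifference_ks) < np.median(np.log(indifference_ks))).astype(float)
            fit_indifference_point(y, indifference_ks)


class TestClassifyPattern:
    def test_mono_choice_patterns(self):
        amounts = np.linspace(10, 96, 32)
        assert classify_pattern(np.zeros(32), amounts) == "all_ss"
        assert classify_pattern(np.ones(32), amounts) == "all_ll"

    def test_anti_monotone_in_amount_is_inconsistent(self):
        amounts = np.linspace(10, 96, 32)
        y = (amounts < 30).astype(float)  # LL only for the smallest LL amounts
        assert classify_pattern(y, amounts) == "inconsistent"

    def test_amount_independent_noise_is_fit_ok(self):
        rng = np.random.default_rng(2)
        amounts = np.linspace(10, 96, 32)
        assert classify_pattern((rng.random(32) < 0.5).astype(float), amounts) == "fit_ok"


class TestImputation:
    def test_mono_choice_rules_use_group_extremes(self):
        ref = [-3.0, -2.5, -2.0]
        assert impute_log_k("all_ss", ref) == (-2.0, "impute_max")
        assert impute_log_k("all_ll", ref) == (-3.0, "impute_min")

    def test_inconsistent_interpolates_pct_ss_line(self):
        tab = pd.DataFrame({"pct_ss": [0.25, 0.75], "log_k": [-3.0, -1.0]})
        val, method = impute_log_k("inconsistent", [-3.0, -1.0], pct_ss=0.5,
                                   group_pct_ss_table=tab)
        assert val == pytest.approx(-2.0)
        assert method == "interpolate_pct_ss"

    def test_insufficient_reference_raises(self):
        with pytest.raises(CannotImputeError):
            impute_log_k("all_ss", [-2.0])
        with pytest.raises(ValueError):
            impute_log_k("fit_ok", [-3.0, -2.0])

    def test_imputed_values_bracket_fitted_group(self, default_cohort):
        _, choices, _, _ = default_cohort
        est = estimate_participants(choices)
        for _, sub in est.groupby(["group", "reward_type"]):
            fitted = sub[sub["method"] == "logistic_fit"]["log_k"]
            if fitted.empty:
                continue
            hi = sub[sub["method"] == "impute_max"]["log_k"]
            lo = sub[sub["method"] == "impute_min"]["log_k"]
            assert (hi >= fitted.max() - 1e-12).all()
            assert (lo <= fitted.min() + 1e-12).all()


class TestSensitivity:
    def test_coin_flips_have_near_zero_amount_slope(self, design):
        rng = np.random.default_rng(4)
        frame = pd.concat([design_to_frame(design)] * 10, ignore_index=True)
        import statsmodels.api as sm
        X = sm.add_constant(frame[["ll_amount", "ll_delay"]].to_numpy())
        within = []
        for _ in range(20):
            y = (rng.random(len(frame)) < 0.5).astype(float)
            est = estimate_sensitivity(y, frame)
            # statsmodels Logit is the independent MLE oracle (coef + SE)
            ref = sm.Logit(y, X).fit(disp=0)
            assert est.beta_amount == pytest.approx(ref.params[1], abs=1e-5)
            within.append(abs(est.beta_amount) < 2 * ref.bse[1])
        assert np.mean(within) >= 0.8  # |beta| < 2 SE for ~95% of null draws

    def test_hyperbolic_choosers_have_positive_sensitivity(self, design):
        rng = np.random.default_rng(6)
        frame = design_to_frame(design)
        signs = []
        for _ in range(300):
            y = simulate_choices(rng.uniform(-4, -1), 2.0, design, rng)
            if y.min() == y.max():
                continue
            signs.append(estimate_sensitivity(y, frame).beta_amount > 0)
        assert np.mean(signs) > 0.95

    def test_anti_consistent_chooser_negative_and_capped_under_separation(self, design):
        frame = design_to_frame(design)
        y = (frame["ll_amount"] < frame["ll_amount"].median()).astype(float).to_numpy()
        est = estimate_sensitivity(y, frame)
        assert est.beta_amount < 0

    def test_constant_predictors_rejected(self):
        frame = pd.DataFrame({"ll_amount": [10.0] * 8, "ll_delay": range(8)})
        with pytest.raises(ValueError):
            estimate_sensitivity(np.tile([0, 1], 4), frame)


class TestScaleAndOutliers:
    @pytest.mark.parametrize("log_k, k_2dp", [(-2.11, 0.12), (-3.05, 0.05),
                                              (-1.54, 0.21), (-2.22, 0.11)])
    def test_natural_log_correspondences(self, log_k, k_2dp):
        assert round(log_k_to_k(log_k), 2) == k_2dp

    def test_log_k_to_k_at_zero(self):
        assert log_k_to_k(0.0) == pytest.approx(1.0)

    def test_triple_iqr_fences(self):
        kept, removed = remove_extreme_outliers([1, 2, 3, 4, 100])
        assert list(removed) == [4]
        assert list(kept) == [1, 2, 3, 4]

    def test_constant_and_inlier_samples_untouched(self):
        kept, removed = remove_extreme_outliers([5.0] * 6)
        assert len(removed) == 0 and list(kept) == [5.0] * 6
        kept, removed = remove_extreme_outliers([1.0, 2.0, 3.0, 4.0])
        assert len(removed) == 0

    def test_tiny_sample_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            kept, removed = remove_extreme_outliers([1.0, 2.0, 1000.0])
        assert len(removed) == 0 and len(kept) == 3


class TestCohortLevelProperties:
    def test_clean_cohort_mostly_fit_ok(self, clean_estimates200):
        # the inconsistency screen has a one-sided alpha=0.05; honest noisy
        # choosers may be flagged at up to roughly that rate
        frac = (clean_estimates200["responder_class"] == "fit_ok").mean()
        assert frac >= 0.95
        assert set(clean_estimates200["responder_class"]) <= {"fit_ok", "inconsistent"}

    def test_discounting_couples_negatively_to_ll_sensitivity(self, clean_estimates200):
        from itcmed.stats import group_residual_correlation
        sub = clean_estimates200[clean_estimates200["reward_type"] == "money"]
        sub = sub.dropna(subset=["log_k", "beta_amount"])
        res = group_residual_correlation(sub["log_k"], sub["beta_amount"],
                                         sub["group"])
        assert res.rho < 0
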