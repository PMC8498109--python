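"""Logistic engine: MLE against independent oracles, calibration, discrimination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ghdpretest import (
    SeparationError,
    fit_logistic,
    hosmer_lemeshow,
    roc_auc,
)
from ghdpretest.logit import DegenerateGroupsError

from conftest import exhaustive_auc, grid_search_logistic


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # single binary predictor: slope is the log cross-product ratio and
        # its Wald SE is sqrt(1/a + 1/b + 1/c + 1/d); counts are the study's
        # deficits-by-diagnosis table (39/8 with deficits, 15/18 without)
        a, b, c, d = 39, 8, 15, 18
        x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
        y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
        fit = fit_logistic(x[:, None], y)
        assert fit.coef[1] == pytest.approx(math.log(a * d / (b * c)), abs=1e-8)
        assert fit.coef[1] == pytest.approx(1.766, abs=1e-3)
        assert math.exp(fit.coef[1]) == pytest.approx(5.85, abs=0.01)
        assert fit.se[1] == pytest.approx(math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-8)
        assert fit.converged

    def test_symmetric_null_gives_zero_coefficients(self):
        # identical predictor distribution in both classes, balanced outcome
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        fit = fit_logistic(x[:, None], y)
        assert fit.coef == pytest.approx([0.0, 0.0], abs=1e-8)

    def test_matches_grid_search_oracle_on_small_fixture(self):
        x = np.array([-1.2, -0.5, 0.1, 0.4, 0.8, 1.3, 1.9, 2.5])
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1])
        b0, b1 = grid_search_logistic(x, y)
        fit = fit_logistic(x[:, None], y)
        assert fit.coef[0] == pytest.approx(b0, abs=1e-3)
        assert fit.coef[1] == pytest.approx(b1, abs=1e-3)

    def test_score_equations_hold_at_mle(self, large_cohort):
        from ghdpretest.pipeline import design_from_cohort

        X, y = design_from_cohort(large_cohort)
        fit = fit_logistic(X, y)
        residual = y - fit.predict(X)
        assert abs(residual.sum()) < 1e-6
        assert np.abs(X.T @ residual).max() < 1e-6

    def test_agrees_with_statsmodels(self, study_cohort):
        import statsmodels.api as sm

        from ghdpretest.pipeline import design_from_cohort

        X, y = design_from_cohort(study_cohort)
        fit = fit_logistic(X, y)
        reference = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.coef == pytest.approx(reference.params, abs=1e-6)
        assert fit.se == pytest.approx(reference.bse, rel=1e-4)
        assert fit.log_likelihood == pytest.approx(reference.llf, abs=1e-8)

    def test_ci_brackets_or_and_loglik_nonpositive(self, study_cohort):
        from ghdpretest.pipeline import design_from_cohort

        X, y = design_from_cohort(study_cohort)
        fit = fit_logistic(X, y)
        assert fit.log_likelihood <= 0
        assert np.all(fit.ci_lower < fit.odds_ratios)
        assert np.all(fit.odds_ratios < fit.ci_upper)
        assert np.allclose(fit.odds_ratios, np.exp(fit.coef))

    def test_separation_detected(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(SeparationError):
            fit_logistic(x[:, None], y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.arange(4.0)[:, None], np.ones(4))

    def test_collinear_design_rejected(self):
        x = np.arange(6.0)
        X = np.column_stack([x, 2 * x])
        y = np.array([0, 1, 0, 1, 0, 1])
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(X, y)


class TestHosmerLemeshow:
    def test_perfect_calibration_gives_zero(self):
        # each group's observed count equals its expected count exactly
        p = np.repeat([0.25, 0.5, 0.75], 4)
        y = np.array([0, 0, 0, 1, 0, 0, 1, 1, 0, 1, 1, 1])
        result = hosmer_lemeshow(p, y, groups=3)
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_group_hand_computation(self):
        # two groups of 5: E=1 (O=2) and E=4 (O=3) -> 1/0.8 + 1/0.8 = 2.5
        p = np.array([0.2] * 5 + [0.8] * 5)
        y = np.array([1, 1, 0, 0, 0, 1, 1, 1, 0, 0])
        result = hosmer_lemeshow(p, y, groups=2)
        assert result.statistic == pytest.approx(2.5, abs=1e-12)
        assert result.n_groups == 2
        assert result.df == 0
        assert math.isnan(result.p_value)

    def test_ten_group_hand_computation(self):
        # ten tied groups of 4 with p_g = g/11; statistic frozen from a hand
        # evaluation of sum (O-E)^2 / (E (1 - E/m))
        p = np.repeat([g / 11 for g in range(1, 11)], 4)
        y = np.zeros(40)
        observed = [0, 1, 1, 1, 2, 2, 3, 3, 4, 4]
        start = 0
        for count in observed:
            y[start : start + count] = 1
            start += 4
        result = hosmer_lemeshow(p, y, groups=10)
        assert result.statistic == pytest.approx(2.3478174603174606, abs=1e-10)
        assert result.df == 8
        assert result.p_value == pytest.approx(0.96845, abs=1e-4)

    def test_invariant_to_within_group_reordering(self):
        rng = np.random.default_rng(1)
        p = np.repeat([0.1, 0.3, 0.6, 0.9], 5)
        y = rng.integers(0, 2, size=20).astype(float)
        base = hosmer_lemeshow(p, y, groups=4).statistic
        for _ in range(5):
            perm = rng.permutation(20)
            assert hosmer_lemeshow(p[perm], y[perm], groups=4).statistic == pytest.approx(base)

    def test_statistic_grows_with_miscalibration(self, study_cohort):
        # degrade calibration by an additive logit shift; statistic is
        # monotone in the shift magnitude on a fixed fixture
        from ghdpretest.pipeline import design_from_cohort

        X, y = design_from_cohort(study_cohort)
        fit = fit_logistic(X, y)
        p = fit.predict(X)
        logit = np.log(p / (1 - p))
        stats = []
        for shift in [0.0, 0.75, 1.5, 2.25]:
            shifted = 1 / (1 + np.exp(-(logit + shift)))
            stats.append(hosmer_lemeshow(shifted, y, groups=10).statistic)
        assert stats == sorted(stats)

    def test_all_tied_probabilities_degenerate(self):
        with pytest.raises(DegenerateGroupsError):
            hosmer_lemeshow(np.full(20, 0.5), np.ones(20), groups=4)

    def test_probabilities_must_be_interior(self):
        with pytest.raises(ValueError, match="strictly inside"):
            hosmer_lemeshow(np.array([0.0, 0.5, 0.9, 0.2]), np.array([0, 1, 1, 0]), groups=2)


class TestRocAuc:
    def test_four_pair_enumeration(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert roc_auc(np.full(10, 0.3), [0, 1] * 5) == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        scores = np.concatenate([np.arange(5), np.arange(10, 15)])
        y = np.concatenate([np.zeros(5), np.ones(5)])
        assert roc_auc(scores, y) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        scores = rng.choice(np.linspace(0, 1, 15), size=n)  # force ties
        y = rng.integers(0, 2, size=n).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert roc_auc(scores, y) == pytest.approx(exhaustive_auc(scores, y), abs=1e-12)

    def test_agrees_with_sklearn(self, study_cohort):
        from sklearn.metrics import roc_auc_score

        from ghdpretest.pipeline import design_from_cohort

        X, y = design_from_cohort(study_cohort)
        scores = X @ np.array([-1.27, 1.82])
        assert roc_auc(scores, y) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    @given(st.data())
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_invariance_and_reflection(self, data):
        n = data.draw(st.integers(6, 30))
        # well-separated distinct scores so monotone transforms cannot
        # collapse neighbours through floating-point rounding
        ints = data.draw(
            st.lists(st.integers(-60, 60), min_size=n, max_size=n, unique=True)
        )
        scores = np.array(ints, dtype=float) / 7.0
        y = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if y.min() == y.max():
            y[0] = 1 - y[0]
        base = roc_auc(scores, y)
        # strictly increasing transform leaves the AUC unchanged
        assert roc_auc(np.exp(scores / 3) + scores, y) == pytest.approx(base, abs=1e-12)
        # negation reflects it (no ties by construction)
        assert roc_auc(-scores, y) == pytest.approx(1.0 - base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])
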