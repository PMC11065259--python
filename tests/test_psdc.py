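"""Serodifference curve: both functional forms, grid search, MCMC.

Expected values marked "oracle" were computed with 30-digit arbitrary-
precision arithmetic (sympy) from the closed-form expressions.
"""
import numpy as np
import pytest

from tbsdc.psdc import (
    DomainError,
    PsdcCurveModel,
    SurveyPoint,
    backcalc_psdc,
    fixed_alpha_fit,
    grid_search_alpha,
    mcmc_alpha,
    psdc,
    sse_objective,
)
from tbsdc.simulate import gen_survey_points


class TestCurve:
    def test_half_prevalence_alpha_one_limit(self):
        # both readings coincide at P = 1/2 when alpha -> 1: (1/4)/0.5 = 0.25^0.5
        assert psdc(0.5, 1 - 1e-12, "ratio") == pytest.approx(0.5, abs=1e-9)
        assert psdc(0.5, 1 - 1e-12, "exponent") == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("P,alpha,form,expected", [
        (0.3, 0.829, "ratio", 0.914110169727021784510212656662),
        (0.33, 0.829, "ratio", 0.867261620548324920004859025196),
        (0.5, 0.9, "ratio", 0.574349177498517503399313473389),
        (0.3, 0.829, "exponent", 0.678322055986264848814068248348),
        (0.1, 0.6, "exponent", 0.865475046131110077836508538864),
        (0.01, 0.829, "exponent", 0.962462496623771055802702357258),
    ])
    def test_against_high_precision_oracle(self, P, alpha, form, expected):
        assert psdc(P, alpha, form) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("P", [0.01, 0.03])
    def test_ratio_form_clamps_at_one_for_small_prevalence(self, P):
        # raw values are 2.1796... and 1.7760... (oracle); the clamp binds
        assert psdc(P, 0.829, "ratio") == 1.0

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(DomainError):
                psdc(bad, 0.5)
        for bad_alpha in (0.0, 1.0, -0.1):
            with pytest.raises(DomainError):
                psdc(0.2, bad_alpha)

    @pytest.mark.parametrize("alpha", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_exponent_form_strictly_decreasing_in_prevalence(self, alpha):
        grid = np.linspace(0.005, 0.95, 400)
        vals = psdc(grid, alpha, "exponent")
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("alpha", [0.3, 0.6, 0.9])
    def test_ratio_form_decreasing_where_unclamped(self, alpha):
        grid = np.linspace(0.005, 0.95, 400)
        vals = psdc(grid, alpha, "ratio")
        unclamped = vals < 1.0
        assert np.all(np.diff(vals[unclamped]) < 0)

    def test_vectorized_over_alpha_draws(self):
        alphas = np.array([0.3, 0.5, 0.7])
        vals = psdc(0.2, alphas)
        assert vals.shape == (3,)
        assert np.all(np.diff(vals) < 0)  # decreasing in alpha


class TestObjective:
    def test_zero_when_points_on_curve(self):
        pts = gen_survey_points(0.6, 19, noise_sd=0.0, seed=4)
        assert sse_objective(pts, 0.6) == pytest.approx(0.0, abs=1e-24)

    def test_known_residuals(self):
        pts = [
            SurveyPoint(0.2, psdc(0.2, 0.5) + 0.1),
            SurveyPoint(0.3, psdc(0.3, 0.5) - 0.2),
        ]
        assert sse_objective(pts, 0.5) == pytest.approx(0.05)

    def test_weights_scale_terms(self):
        pts = [SurveyPoint(0.2, psdc(0.2, 0.5) + 0.1, weight=3.0)]
        assert sse_objective(pts, 0.5) == pytest.approx(0.03)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            sse_objective([], 0.5)


class TestGridSearch:
    @pytest.mark.parametrize("alpha_true", [0.6, 0.58, 0.34])
    def test_exact_recovery_on_noise_free_points(self, alpha_true):
        pts = gen_survey_points(alpha_true, 19, noise_sd=0.0, seed=11)
        fit = grid_search_alpha(pts)
        assert fit.alpha_hat == pytest.approx(alpha_true, abs=1e-9)
        assert fit.sse == pytest.approx(0.0, abs=1e-20)

    def test_stage2_grid_reproduces_documented_window(self):
        pts = gen_survey_points(0.8, 19, noise_sd=0.0, seed=12)
        fit = grid_search_alpha(pts)
        stage2 = [a for a, _ in fit.grid_stage2]
        assert stage2 == pytest.approx(np.arange(0.72, 0.8801, 0.02))

    def test_equals_brute_force_over_union_of_grids(self):
        pts = gen_survey_points(0.55, 19, noise_sd=0.04, seed=13)
        fit = grid_search_alpha(pts)
        union = sorted({a for a, _ in fit.grid_stage1} | {a for a, _ in fit.grid_stage2})
        brute = min(union, key=lambda a: (sse_objective(pts, a), a))
        # the two-stage winner cannot be beaten anywhere on the union it saw
        assert sse_objective(pts, fit.alpha_hat) <= sse_objective(pts, brute) + 1e-15

    def test_stage2_winner_not_worse_than_stage1(self):
        pts = gen_survey_points(0.47, 19, noise_sd=0.05, seed=14)
        fit = grid_search_alpha(pts)
        assert fit.sse <= min(s for _, s in fit.grid_stage1) + 1e-15

    def test_tie_breaks_to_smaller_alpha(self):
        # observations midway between the curves at 0.3 and 0.7 give (near-)
        # equal objectives; on an exact tie the smaller alpha must win
        pts = [
            SurveyPoint(P, (psdc(P, 0.3) + psdc(P, 0.7)) / 2)
            for P in (0.2, 0.4)
        ]
        s3, s7 = sse_objective(pts, 0.3), sse_objective(pts, 0.7)
        fit = grid_search_alpha(pts, stage1=[0.3, 0.7], stage2_halfwidth=0.0)
        assert fit.alpha_hat == (0.3 if s3 <= s7 else 0.7)

    def test_identical_prevalences_rejected(self):
        pts = [SurveyPoint(0.2, 0.5), SurveyPoint(0.2, 0.6)]
        with pytest.raises(ValueError, match="unidentifiable"):
            grid_search_alpha(pts)


class TestMcmc:
    def test_same_seed_same_chain(self):
        pts = gen_survey_points(0.6, 19, noise_sd=0.03, seed=21)
        f1 = mcmc_alpha(pts, init=0.6, chain_length=2000, burn_in=200, seed=77)
        f2 = mcmc_alpha(pts, init=0.6, chain_length=2000, burn_in=200, seed=77)
        assert f1.posterior_mean == f2.posterior_mean
        np.testing.assert_array_equal(f1.chain, f2.chain)

    def test_vanishing_noise_collapses_to_least_squares(self):
        pts = gen_survey_points(0.6, 19, noise_sd=1e-4, seed=22)
        grid = grid_search_alpha(pts)
        f = mcmc_alpha(pts, init=grid.alpha_hat, seed=22)
        assert abs(f.posterior_mean - grid.alpha_hat) < 0.005

    def test_invalid_arguments(self):
        pts = gen_survey_points(0.6, 19, noise_sd=0.03, seed=23)
        with pytest.raises(DomainError):
            mcmc_alpha(pts, init=1.2)
        with pytest.raises(ValueError):
            mcmc_alpha(pts, init=0.5, chain_length=100, burn_in=100)


class TestModelObject:
    def test_fit_returns_grid_and_posterior(self):
        pts = gen_survey_points(0.6, 19, noise_sd=0.03, seed=31)
        fit = PsdcCurveModel(pts).fit(chain_length=3000, burn_in=300, seed=5)
        assert 0 < fit.alpha_hat < 1
        lo, hi = fit.posterior_ui
        assert lo <= fit.posterior_mean <= hi
        assert "alpha" in fit.summary()

    def test_from_dataframe(self):
        import pandas as pd

        pts = gen_survey_points(0.5, 10, noise_sd=0.0, seed=32)
        df = pd.DataFrame({"prevalence": [p.prevalence for p in pts],
                           "p_sdc": [p.p_sdc for p in pts]})
        fit = PsdcCurveModel(df).fit(mcmc=False)
        assert fit.alpha_hat == pytest.approx(0.5, abs=1e-9)


class TestBackcalc:
    def test_matches_curve_at_fitted_alpha(self):
        fit = fixed_alpha_fit(0.829, form="ratio")
        assert backcalc_psdc(0.33, fit) == pytest.approx(
            0.867261620548324920004859025196, rel=1e-12)
        assert backcalc_psdc(0.03, fit) == 1.0  # clamped (raw oracle 1.776...)

    def test_exponent_form_default(self):
        fit = fixed_alpha_fit(0.829)
        assert fit.form == "exponent"
        assert backcalc_psdc(0.3, fit) == pytest.approx(
            0.678322055986264848814068248348, rel=1e-12)
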