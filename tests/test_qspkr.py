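"""QSPkR regression: design matrices, OLS statistics, reference models."""

import numpy as np
import pytest
from scipy import optimize

from zfpk.core_data import CompoundDescriptor
from zfpk.qspkr import (
    Centering,
    ModelSpec,
    PARABOLIC_TERMS,
    RankDeficiencyError,
    build_design,
    centered_quadratic,
    evaluate_model,
    fit_model,
    fit_reference_suite,
    intercept,
    linear,
    ols_fit,
)

PARABOLIC = ModelSpec("RE", PARABOLIC_TERMS)


def _toy(name, logd, mr=100.0, tpsa=50.0):
    return CompoundDescriptor(
        name=name, mw=400.0, rotor=5, hba=3, hbd=1, mr=mr, tpsa=tpsa, logd=logd
    )


class TestCenteringConstants:
    def test_logd_sample_mean_matches_printed_centering_constant(self, descriptors):
        mean = np.mean([d.logd for d in descriptors])
        assert mean == pytest.approx(-0.1771, abs=5e-4)
        # the printed equations center at (Log D + 0.179)
        assert abs(-mean - 0.179) <= 0.005

    def test_mr_sample_mean_matches_printed_centering_constant(self, descriptors):
        mean = np.mean([d.mr for d in descriptors])
        assert abs(mean - 166.591) <= 0.005

    def test_already_centered_descriptor_gives_raw_quadratic(self):
        logds = [-2.0, -1.0, 0.0, 1.0, 2.0]  # mean exactly zero
        comps = [_toy(f"C{i}", x) for i, x in enumerate(logds)]
        X, labels, centers = build_design(comps, PARABOLIC)
        assert centers["logd"] == 0.0
        np.testing.assert_allclose(X[:, 2], np.array(logds) ** 2)

    def test_fixed_centering_uses_supplied_constants(self, descriptors):
        spec = ModelSpec(
            "RE", PARABOLIC_TERMS, Centering.FIXED, (("logd", -0.179),)
        )
        X, _, centers = build_design(descriptors, spec)
        assert centers["logd"] == -0.179
        logd = np.array([d.logd for d in descriptors])
        np.testing.assert_allclose(X[:, 2], (logd + 0.179) ** 2)


class TestOLS:
    def test_exact_parabola_recovered_perfectly(self):
        comps = [_toy(f"C{i}", x) for i, x in enumerate([-2, -1, 0, 0.5, 1, 1.5, 2])]
        y = np.array([0.3 - 0.1 * c.logd + 0.25 * c.logd**2 for c in comps])
        fit = fit_model(comps, y, PARABOLIC)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_rest_of_body_refit_matches_published_statistics(
        self, descriptors, reference_exposure_df
    ):
        y = reference_exposure_df["re_rob"].to_numpy()
        fit = fit_model(descriptors, y, PARABOLIC)
        assert fit.rmse == pytest.approx(0.299, abs=0.02)
        assert fit.r2_adj == pytest.approx(0.82, abs=0.05)
        assert fit.n == 7 and fit.p == 3

    def test_whole_body_refit_rmse(self, descriptors, reference_exposure_df):
        y = reference_exposure_df["re_wb"].to_numpy()
        fit = fit_model(descriptors, y, PARABOLIC)
        assert fit.sse == pytest.approx(0.1794, abs=0.01)
        assert fit.rmse == pytest.approx(0.212, abs=0.005)
        assert fit.r2 == pytest.approx(0.81, abs=0.05)

    def test_constant_column_raises_rank_deficiency(self):
        comps = [_toy(f"C{i}", 1.0) for i in range(5)]  # identical Log D
        with pytest.raises(RankDeficiencyError):
            build_design(comps, PARABOLIC)

    def test_more_parameters_than_points_rejected(self):
        comps = [_toy(f"C{i}", x) for i, x in enumerate([0.0, 1.0, 2.0])]
        X, labels, centers = build_design(comps, PARABOLIC)
        with pytest.raises(ValueError, match="n > p"):
            ols_fit(X[:2], np.zeros(2), PARABOLIC, labels, centers)

    def test_residuals_orthogonal_to_design(self, descriptors, reference_exposure_df):
        y = reference_exposure_df["re_rob"].to_numpy()
        X, labels, centers = build_design(descriptors, PARABOLIC)
        fit = ols_fit(X, y, PARABOLIC, labels, centers)
        beta = np.array([b for _, b in fit.coefficients])
        residuals = y - X @ beta
        np.testing.assert_allclose(X.T @ residuals, 0.0, atol=1e-8)

    def test_coefficients_match_nelder_mead_sse_minimizer(
        self, descriptors, reference_exposure_df
    ):
        """Independent oracle: direct SSE minimization must land on the
        same coefficients as the linear-algebra solution."""
        y = reference_exposure_df["re_wb"].to_numpy()
        X, labels, centers = build_design(descriptors, PARABOLIC)
        fit = ols_fit(X, y, PARABOLIC, labels, centers)
        beta_hat = np.array([b for _, b in fit.coefficients])

        def sse(beta):
            r = y - X @ beta
            return r @ r

        res = optimize.minimize(
            sse, np.zeros(3), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000},
        )
        np.testing.assert_allclose(res.x, beta_hat, atol=1e-4)

    def test_fit_quality_invariant_to_centering_choice(
        self, descriptors, reference_exposure_df
    ):
        """Centering shifts coefficients but spans the same column space,
        so SSE, R^2 and RMSE must not change."""
        y = reference_exposure_df["re_rob"].to_numpy()
        raw = ModelSpec("RE", PARABOLIC_TERMS, Centering.FIXED, (("logd", 0.0),))
        f_centered = fit_model(descriptors, y, PARABOLIC)
        f_raw = fit_model(descriptors, y, raw)
        assert f_raw.sse == pytest.approx(f_centered.sse, rel=1e-9)
        assert f_raw.r2 == pytest.approx(f_centered.r2, rel=1e-9)
        assert f_raw.rmse == pytest.approx(f_centered.rmse, rel=1e-9)
        b_raw = dict(f_raw.coefficients)
        b_cen = dict(f_centered.coefficients)
        assert b_raw["logd"] != pytest.approx(b_cen["logd"], abs=1e-6)


PRINTED_WB = [-0.011, 0.187, 0.169]
PRINTED_WB_SPEC = ModelSpec(
    "RE_WB", PARABOLIC_TERMS, Centering.FIXED, (("logd", -0.179),)
)


class TestEvaluateModel:
    def test_printed_model_at_extreme_lipophilicity(self):
        c = _toy("X", 1.73)
        value = evaluate_model(PRINTED_WB, PRINTED_WB_SPEC, c, {"logd": -0.179})
        assert value == pytest.approx(0.928, abs=5e-4)

    def test_quadratic_vanishes_at_the_centering_point(self):
        c = _toy("X", -0.179)
        value = evaluate_model(PRINTED_WB, PRINTED_WB_SPEC, c, {"logd": -0.179})
        assert value == pytest.approx(-0.011 + 0.187 * -0.179)

    def test_zero_coefficients_give_zero_prediction(self):
        c = _toy("X", 1.0)
        assert evaluate_model([0, 0, 0], PRINTED_WB_SPEC, c, {"logd": -0.179}) == 0.0

    def test_coefficient_count_mismatch_rejected(self):
        c = _toy("X", 1.0)
        with pytest.raises(ValueError, match="coefficients"):
            evaluate_model([0, 0], PRINTED_WB_SPEC, c, {"logd": -0.179})

    def test_printed_coefficients_sse_against_published_responses(
        self, descriptors, reference_exposure_df
    ):
        y = reference_exposure_df["re_wb"].to_numpy()
        preds = np.array(
            [
                evaluate_model(PRINTED_WB, PRINTED_WB_SPEC, d, {"logd": -0.179})
                for d in descriptors
            ]
        )
        sse = float(((preds - y) ** 2).sum())
        assert 0.16 <= sse <= 0.20


class TestReferenceSuite:
    @pytest.fixture()
    def fits(self, descriptors, reference_exposure_summaries):
        with pytest.warns(UserWarning, match="residual degrees of freedom"):
            return fit_reference_suite(descriptors, reference_exposure_summaries)

    def test_bookkeeping(self, fits):
        assert fits["RE_RoB"].n == 7 and fits["RE_RoB"].p == 3
        assert fits["RE_Yolk"].p == 5

    def test_predictions_rise_steeply_above_the_lipophilicity_cutoff(
        self, fits, descriptors
    ):
        fit = fits["RE_WB"]
        hi = evaluate_model(fit, fit.spec, _toy("hi", 1.73))
        mid = evaluate_model(fit, fit.spec, _toy("mid", 1.0))
        assert hi > mid

    def test_yolk_model_near_saturated_fit(self, fits):
        assert fits["RE_Yolk"].rmse < 2 * 0.043
        assert fits["RE_Yolk"].r2 > 0.95
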