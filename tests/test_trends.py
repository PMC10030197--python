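"""Trend reconstruction: standardization, LMM fits, model averaging, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ssf_assess as sa
from ssf_assess.trends import (FitResult, ModelSpec, Standardizer, average_models,
                               diagnostics, enumerate_models, fit_lmm,
                               fit_transforms, predict_trend)


class TestStandardize:
    def test_symmetric_triple(self):
        np.testing.assert_allclose(sa.standardize([1, 2, 3]), [-1, 0, 1], atol=1e-12)

    def test_two_values_use_sample_sd(self):
        np.testing.assert_allclose(sa.standardize([10, 20]), [-0.7071, 0.7071], atol=1e-4)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30, unique=True))
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_with_unit_moments(self, xs):
        z = sa.standardize(xs)
        np.testing.assert_allclose(sa.standardize(z), z, atol=1e-9)
        assert z.mean() == pytest.approx(0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            sa.standardize([4.0, 4.0, 4.0])

    def test_transform_is_remembered_for_new_data(self):
        s = Standardizer().fit([0.0, 10.0])
        assert s.transform([5.0])[0] == pytest.approx(0.0)


class TestEnumerateModels:
    def test_single_candidate_gives_two_models(self):
        labels = [m.label for m in enumerate_models(["year"])]
        assert labels == ["1", "year"]

    def test_three_candidates_give_all_subsets(self):
        specs = enumerate_models()
        assert len(specs) == 8
        assert len({s.fixed_terms for s in specs}) == 8

    def test_year_interactions_respect_marginality(self):
        specs = enumerate_models(interactions="with_year")
        assert len(specs) == 13
        for s in specs:
            for t in s.fixed_terms:
                if ":" in t:
                    a, b = t.split(":")
                    assert a in s.fixed_terms and b in s.fixed_terms

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(("year", "year"))


def _mk_fit(terms, coefs, ses, aic):
    names = ("intercept",) + tuple(terms)
    return FitResult(spec=ModelSpec(tuple(terms)),
                     coefficients=dict(zip(names, coefs)),
                     std_errors=dict(zip(names, ses)),
                     cov_fe=np.diag(np.asarray(ses, dtype=float) ** 2),
                     var_fisher=0.1, var_resid=0.1,
                     loglik=-(aic - 2 * (len(names) + 2)) / 2, aic=aic,
                     n_obs=50, n_groups=10)


class TestAverageModels:
    def test_single_model_passes_through(self):
        f = _mk_fit(["year"], [2.0, -0.4], [0.1, 0.05], 100.0)
        avg = sa.average_models([f])
        assert avg.akaike_weights[0] == pytest.approx(1.0)
        assert avg.averaged_coefficients == f.coefficients

    def test_equal_aic_splits_weights_evenly(self):
        fits = [_mk_fit(["year"], [2, -0.4], [0.1, 0.05], 100.0),
                _mk_fit([], [2.2], [0.1], 100.0)]
        avg = sa.average_models(fits)
        np.testing.assert_allclose(avg.akaike_weights, [0.5, 0.5])

    def test_members_selected_and_weighted_by_delta_aic(self):
        fits = [_mk_fit(["year"], [2, -0.4], [0.1, 0.05], 100.0),
                _mk_fit([], [2.2], [0.1], 101.0),
                _mk_fit(["fishing_time"], [2, 0.1], [0.1, 0.1], 110.0)]
        avg = sa.average_models(fits)
        assert len(avg.member_fits) == 2
        np.testing.assert_allclose(avg.akaike_weights, [0.6225, 0.3775], atol=1e-4)
        # full averaging: term absent from a member contributes 0
        w = avg.akaike_weights
        assert avg.averaged_coefficients["year"] == pytest.approx(w[0] * -0.4)
        assert avg.term_importance["year"] == pytest.approx(w[0])

    def test_weights_invariant_to_aic_shift(self):
        fits = [_mk_fit([], [1.0], [0.1], a) for a in (100.0, 101.5, 103.0)]
        shifted = [_mk_fit([], [1.0], [0.1], a + 37.0) for a in (100.0, 101.5, 103.0)]
        np.testing.assert_allclose(sa.average_models(fits).akaike_weights,
                                   sa.average_models(shifted).akaike_weights, atol=1e-12)

    def test_averaging_shrinks_toward_zero(self):
        fits = [_mk_fit(["year"], [2, -0.5], [0.1, 0.05], 100.0),
                _mk_fit([], [2.1], [0.1], 100.5)]
        avg = sa.average_models(fits)
        assert abs(avg.averaged_coefficients["year"]) <= 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sa.average_models([])


class TestFitLmm:
    def test_constant_catch_gives_zero_slopes(self):
        n = 40
        data = pd.DataFrame({
            "fisher_id": np.repeat([f"F{i}" for i in range(10)], 4),
            "year_assigned": np.tile([1990, 2000, 2010, 2020], 10),
            "catch_kg": 12.0,
            "fishing_time_hr": np.linspace(4, 8, n),
            "gillnet_length_m": np.linspace(50, 150, n),
        })
        fit = fit_lmm(ModelSpec(("year",)), data)
        assert fit.coefficients["year"] == pytest.approx(0.0, abs=1e-8)
        assert fit.var_resid == pytest.approx(0.0, abs=1e-8)

    def test_balanced_two_group_variance_matches_anova_estimator(self):
        rng = np.random.default_rng(0)
        m, d = 12, 0.8
        y = np.concatenate([3.0 + d + rng.normal(0, 0.05, m),
                            3.0 - d + rng.normal(0, 0.05, m)])
        data = pd.DataFrame({
            "fisher_id": np.repeat(["A", "B"], m),
            "catch_kg": np.exp(y),
            "year_assigned": np.tile(np.arange(m), 2) + 2000,
            "fishing_time_hr": 6.0, "gillnet_length_m": 100.0,
        })
        fit = fit_lmm(ModelSpec(()), data)
        gm = [y[:m].mean(), y[m:].mean()]
        msb = m * sum((g - np.mean(y)) ** 2 for g in gm) / 1
        msw = (np.var(y[:m], ddof=1) + np.var(y[m:], ddof=1)) / 2
        anova_est = (msb - msw) / m
        assert fit.var_fisher == pytest.approx(anova_est, rel=1e-2)

    def test_aic_identity(self, small_frames):
        periods, _, _ = small_frames
        fit = fit_lmm(ModelSpec(("year",)), periods, reml=False)
        k = 2 + 2  # intercept + slope + two variance components
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)

    def test_nonpositive_catch_rejected(self, small_frames):
        periods, _, _ = small_frames
        bad = periods.copy()
        bad.loc[0, "catch_kg"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_lmm(ModelSpec(("year",)), bad)


class TestPercentDecline:
    @pytest.mark.parametrize("first,last,expected", [(26, 9, 65), (190, 30, 84),
                                                     (200, 40, 80), (7.5, 7.5, 0)])
    def test_reported_rounding(self, first, last, expected):
        assert sa.percent_decline(first, last) == expected

    def test_unrounded_value_available(self):
        assert sa.percent_decline(26, 9, rounded=False) == pytest.approx(65.3846, abs=1e-3)

    def test_nonpositive_first_rejected(self):
        with pytest.raises(ValueError):
            sa.percent_decline(0.0, 5.0)


class TestPredictTrend:
    def _transforms(self):
        return {"year": Standardizer().fit(np.arange(1990, 2021))}

    def test_zero_year_effect_gives_flat_line(self):
        avg = sa.average_models([_mk_fit([], [1.7], [0.05], 10.0)])
        pred = predict_trend(avg, [1990, 2005, 2020], self._transforms())
        np.testing.assert_allclose(pred.predicted_catch_kg, np.exp(1.7))

    def test_negative_year_effect_is_strictly_decreasing_and_banded(self):
        avg = sa.average_models([_mk_fit(["year"], [2.0, -0.6], [0.05, 0.02], 10.0)])
        pred = predict_trend(avg, np.arange(1990, 2021), self._transforms())
        assert np.all(np.diff(pred.predicted_catch_kg) < 0)
        assert np.all(pred.predicted_catch_kg > 0)
        assert np.all(pred.ci_low <= pred.predicted_catch_kg)
        assert np.all(pred.predicted_catch_kg <= pred.ci_high)

    def test_noise_free_predictions_match_closed_form(self):
        cfg = sa.SimConfig(n_fishers=30, sigma_fisher=0, sigma_resid=0,
                           beta_time=0, beta_net=0, seed=4)
        survey, truth = sa.simulate_survey(cfg)
        periods = sa.periods_frame(survey)
        tr = fit_transforms(periods, ["year"])
        fit = fit_lmm(ModelSpec(("year",)), periods, transforms=tr)
        avg = sa.average_models([fit])
        years = np.array([1980.0, 2000.0, 2019.0])
        pred = predict_trend(avg, years, tr)
        expected = np.exp(cfg.baseline_log_catch
                          + cfg.beta_year * tr["year"].transform(years))
        np.testing.assert_allclose(pred.predicted_catch_kg, expected, rtol=1e-6)

    def test_missing_year_transform_rejected(self):
        avg = sa.average_models([_mk_fit([], [1.0], [0.1], 10.0)])
        with pytest.raises(ValueError, match="year"):
            predict_trend(avg, [2000], {})


class TestDiagnostics:
    def test_alternating_residuals_give_negative_lag1(self):
        data = pd.DataFrame({"fisher_id": ["A"] * 4,
                             "year_assigned": [2000, 2005, 2010, 2015],
                             "catch_kg": 1.0, "fishing_time_hr": 6.0,
                             "gillnet_length_m": 100.0})
        fit = _mk_fit([], [0.0], [0.1], 10.0)
        fit.fitted = np.zeros(4)
        fit.resid = np.array([1.0, -1.0, 1.0, -1.0])
        rep = diagnostics(fit, data)
        assert rep.lag1_autocorrelation == pytest.approx(-1.0)

    def test_orthogonal_predictors_have_unit_vif(self, small_frames):
        periods, _, _ = small_frames
        fit = fit_lmm(ModelSpec(("year", "gillnet_length", "fishing_time")), periods)
        rep = diagnostics(fit, periods)
        for v in rep.vif.values():
            assert 1.0 <= v < 1.5

    def test_single_term_vif_is_one_by_convention(self, small_frames):
        periods, _, _ = small_frames
        fit = fit_lmm(ModelSpec(("year",)), periods)
        assert diagnostics(fit, periods).vif == {"year": 1.0}

    def test_perfect_collinearity_is_flagged(self, small_frames):
        periods, _, _ = small_frames
        dup = periods.copy()
        dup["gillnet_length_m"] = dup["fishing_time_hr"]
        fit = _mk_fit(["gillnet_length", "fishing_time"], [0, 0.1, 0.1],
                      [0.1, 0.1, 0.1], 10.0)
        fit.fitted = np.zeros(len(dup))
        fit.resid = np.zeros(len(dup))
        rep = diagnostics(fit, dup)
        assert any(f.startswith("collinear") for f in rep.flags)
        assert any(np.isinf(v) for v in rep.vif.values())


def test_regressor_is_sklearn_compatible(small_frames):
    from sklearn.base import clone
    periods, _, _ = small_frames
    reg = sa.CatchTrendRegressor(delta_threshold=2.0)
    cloned = clone(reg)
    assert cloned.get_params()["delta_threshold"] == 2.0
    reg.fit(periods)
    assert set(reg.coef_) >= {"intercept"}
    pred = reg.predict(periods.head(5))
    assert pred.shape == (5,) and np.all(pred > 0)
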