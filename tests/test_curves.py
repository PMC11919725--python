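import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decrypte.curves import (RatioSeries, curve_metrics, curve_metrics_batch,
                             fit_llogistic4, fit_llogistic4_batch, llogistic4,
                             llogistic4_auc, normalize_to_vehicle)

X5 = np.arange(5.0)  # log10 of 1 nM .. 10 uM


class TestNormalizeToVehicle:
    @pytest.mark.parametrize("intensities, vehicle, expected", [
        ((100.0, 200.0), (100.0, 100.0), (1.0, 2.0)),
        ((100.0, 100.0), (100.0,), (1.0, 1.0)),
        ((150.0, 150.0), (90.0, 110.0), (1.5, 1.5)),
    ])
    def test_ratio_is_intensity_over_vehicle_mean(self, intensities, vehicle,
                                                  expected):
        series = normalize_to_vehicle(intensities, (10.0, 100.0), vehicle)
        np.testing.assert_allclose(series.y, expected)
        assert series.fittable

    def test_all_vehicle_missing_marks_series_unfittable(self):
        series = normalize_to_vehicle((1.0, 2.0), (10.0, 100.0),
                                      (np.nan, np.nan))
        assert not series.fittable
        assert fit_llogistic4(series).converged is False

    def test_nonpositive_doses_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_vehicle((1.0, 2.0), (0.0, 10.0), (1.0,))

    def test_missing_vehicle_values_excluded_from_reference(self):
        series = normalize_to_vehicle((50.0,), (10.0,), (100.0, np.nan))
        np.testing.assert_allclose(series.y, [0.5])
        assert series.n_vehicle == 1


class TestFit:
    def test_flat_series_gives_equal_plateaus(self):
        series = RatioSeries(x=X5, y=np.ones(5), n_vehicle=3)
        fit = fit_llogistic4(series)
        assert abs(fit.t - fit.b) < 1e-6
        assert abs(fit.t - 1.0) < 1e-6

    def test_noiseless_parameters_recovered(self):
        true = dict(t=1.0, b=4.0, s=1.0, x0=2.0)
        y = llogistic4(X5, **true)
        fit = fit_llogistic4(RatioSeries(x=X5, y=y, n_vehicle=3))
        for name, v in true.items():
            assert abs(getattr(fit, name) - v) / v < 1e-4

    def test_prediction_at_top_dose_matches_model_formula(self):
        y = llogistic4(X5, 1.0, 4.0, 1.0, 2.0)
        fit = fit_llogistic4(RatioSeries(x=X5, y=y, n_vehicle=3))
        # Y(4) = 4 + (1-4)/(1+10^(4-2))
        assert fit.predict(4.0) == pytest.approx(3.97029702970297, abs=1e-6)

    def test_pec50_is_nine_minus_inflection(self):
        y = llogistic4(X5, 1.0, 0.4, 1.5, 2.5)
        fit = fit_llogistic4(RatioSeries(x=X5, y=y, n_vehicle=3))
        assert fit.pec50_molar == pytest.approx(9.0 - fit.x0)
        assert fit.pec50_molar == pytest.approx(6.5, abs=1e-3)

    def test_too_few_points_yields_sentinel(self):
        y = np.array([1.0, np.nan, np.nan, 2.0, 2.0])
        fit = fit_llogistic4(RatioSeries(x=X5, y=y, n_vehicle=3))
        assert not fit.fittable and not fit.converged
        assert np.isnan(fit.t)

    def test_four_of_five_points_still_fittable(self):
        y = llogistic4(X5, 1.0, 3.0, 1.0, 2.0)
        y[1] = np.nan
        fit = fit_llogistic4(RatioSeries(x=X5, y=y, n_vehicle=3))
        assert fit.fittable
        assert fit.b == pytest.approx(3.0, rel=1e-3)

    def test_slope_constrained_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.lognormal(0, 0.3, 5)
            fit = fit_llogistic4(RatioSeries(x=X5, y=y, n_vehicle=3))
            assert fit.s >= 0.0

    def test_scale_equivariance(self):
        """Multiplying all intensities by a constant leaves everything."""
        inten = np.array([120.0, 110.0, 90.0, 50.0, 40.0])
        veh = np.array([95.0, 105.0, 100.0])
        doses = 10.0 ** X5
        a = normalize_to_vehicle(inten, doses, veh)
        b = normalize_to_vehicle(inten * 37.5, doses, veh * 37.5)
        np.testing.assert_allclose(a.y, b.y)
        fa, fb = fit_llogistic4(a), fit_llogistic4(b)
        assert (fa.t, fa.b, fa.s, fa.x0) == pytest.approx(
            (fb.t, fb.b, fb.s, fb.x0))

    @given(t=st.floats(0.2, 5.0), b=st.floats(0.2, 5.0),
           s=st.floats(0.0, 5.0), x0=st.floats(-1.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_model_predictions_bounded_by_plateaus_and_monotone(self, t, b, s, x0):
        xs = np.linspace(0.0, 4.0, 50)
        y = llogistic4(xs, t, b, s, x0)
        lo, hi = min(t, b), max(t, b)
        assert np.all(y >= lo - 1e-12) and np.all(y <= hi + 1e-12)
        d = np.diff(y)
        assert np.all(d >= -1e-12) or np.all(d <= 1e-12)

    def test_batch_and_scalar_paths_agree_on_clean_curves(self):
        rng = np.random.default_rng(3)
        Y = np.stack([llogistic4(X5, 1.0, 2 ** rng.uniform(-2, 2),
                                 rng.uniform(0.5, 3), rng.uniform(0.5, 3.5))
                      for _ in range(10)])
        batch = fit_llogistic4_batch(X5, Y)
        for i in range(10):
            scalar = fit_llogistic4(RatioSeries(x=X5, y=Y[i], n_vehicle=3))
            np.testing.assert_allclose(
                batch.loc[i, ["t", "b", "s", "x0"]].to_numpy(dtype=float),
                [scalar.t, scalar.b, scalar.s, scalar.x0], rtol=1e-6)


class TestMetrics:
    def test_flat_curve_auc_is_rectangle(self):
        series = RatioSeries(x=X5, y=np.ones(5), n_vehicle=3)
        fit = fit_llogistic4(series)
        met = curve_metrics(fit, series)
        assert met.auc == pytest.approx(4.0, abs=1e-6)

    def test_perfect_fit_has_zero_mad_and_unit_r2(self):
        y = llogistic4(X5, 1.0, 3.0, 1.0, 2.0)
        series = RatioSeries(x=X5, y=y, n_vehicle=3)
        met = curve_metrics(fit_llogistic4(series), series)
        assert met.mad == pytest.approx(0.0, abs=1e-8)
        assert met.r2 == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_auc_matches_fine_trapezoid(self):
        t, b, s, x0 = 1.0, 4.0, 1.0, 2.0
        xs = np.linspace(0.0, 4.0, 10001)
        trap = np.trapezoid(llogistic4(xs, t, b, s, x0), xs)
        assert llogistic4_auc(t, b, s, x0, 0.0, 4.0) == pytest.approx(
            trap, abs=1e-6)

    def test_zero_variance_series_leaves_r2_undefined(self):
        series = RatioSeries(x=X5, y=np.full(5, 2.0), n_vehicle=3)
        met = curve_metrics(fit_llogistic4(series), series)
        assert np.isnan(met.r2)

    def test_curve_fold_change_is_prediction_at_top_dose(self):
        y = llogistic4(X5, 1.0, 4.0, 1.0, 2.0)
        series = RatioSeries(x=X5, y=y, n_vehicle=3)
        fit = fit_llogistic4(series)
        met = curve_metrics(fit, series)
        assert met.curve_fold_change == pytest.approx(fit.predict(4.0))

    def test_linear_slope_matches_polyfit(self):
        y = np.array([1.0, 1.2, 1.1, 1.6, 2.0])
        series = RatioSeries(x=X5, y=y, n_vehicle=3)
        met = curve_metrics(fit_llogistic4(series), series)
        assert met.linear_slope == pytest.approx(np.polyfit(X5, y, 1)[0])

    def test_scalar_polish_never_worse_than_batch(self):
        """On noisy curves the polished scalar path must match or beat the
        batch engine's residual; where they land in the same optimum the
        metrics agree."""
        rng = np.random.default_rng(5)
        Y = rng.lognormal(0, 0.2, (8, 5))
        Y[2, 1] = np.nan
        fits = fit_llogistic4_batch(X5, Y)
        mets = curve_metrics_batch(X5, Y, fits)
        for i in range(8):
            series = RatioSeries(x=X5, y=Y[i], n_vehicle=3)
            scalar_fit = fit_llogistic4(series)
            assert scalar_fit.sse <= fits.loc[i, "sse"] * (1 + 1e-9) + 1e-12
            if scalar_fit.sse == pytest.approx(fits.loc[i, "sse"], rel=1e-6):
                scal = curve_metrics(scalar_fit, series)
                np.testing.assert_allclose(
                    mets.loc[i].to_numpy(dtype=float),
                    [scal.auc, scal.r2, scal.mad, scal.curve_fold_change,
                     scal.linear_slope],
                    rtol=0.02, atol=0.02)
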