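"""Smoothing, error metric and carrying-capacity fitting."""

import numpy as np
import pandas as pd
import pytest

from aedes_capacity import ImfaSeries, fit_K, fit_all_areas, mse, smooth_imfa
from aedes_capacity.synthetic import SyntheticScenario, generate_trap_counts


def make_series(values, n_traps=16, start="2008-01-07"):
    weeks = pd.date_range(start, periods=len(values), freq="7D")
    return ImfaSeries(weeks=weeks, values=np.asarray(values, float), n_traps=n_traps)


class TestSmoothImfa:
    def test_constant_series_unchanged(self):
        s = make_series(np.full(30, 0.5))
        out = smooth_imfa(s)
        np.testing.assert_allclose(out.values, 0.5, atol=1e-12)
        assert out.smoothed

    def test_full_span_reproduces_exact_quadratic(self):
        x = np.arange(25, dtype=float)
        s = make_series(0.02 * x**2 + 0.1 * x + 1.0)
        out = smooth_imfa(s, degree=2, span=1.0)
        np.testing.assert_allclose(out.values, s.values, atol=1e-9)

    def test_noise_reduction_on_seasonal_signal(self):
        rng = np.random.default_rng(12345)
        x = np.arange(104, dtype=float)
        truth = 0.5 + 0.4 * np.sin(2 * np.pi * x / 52)
        raw_sse, smooth_sse = 0.0, 0.0
        for _ in range(100):
            noisy = np.clip(truth + rng.normal(0, 0.15, size=len(x)), 0, None)
            smoothed = smooth_imfa(make_series(noisy), span=0.15).values
            raw_sse += np.sum((noisy - truth) ** 2)
            smooth_sse += np.sum((smoothed - truth) ** 2)
        assert smooth_sse < raw_sse

    def test_negative_fits_clipped_to_zero(self):
        rng = np.random.default_rng(0)
        values = np.clip(rng.normal(0.02, 0.05, 60), 0, None)
        out = smooth_imfa(make_series(values))
        assert np.nanmin(out.values) >= 0.0

    def test_tiny_span_widens_window(self, caplog):
        s = make_series(np.linspace(0, 1, 12))
        with caplog.at_level("WARNING", logger="aedes_capacity.calibration"):
            out = smooth_imfa(s, span=0.01)
        assert "widening" in caplog.text
        assert np.all(np.isfinite(out.values))

    def test_preconditions(self):
        with pytest.raises(ValueError):
            smooth_imfa(make_series(np.ones(5)))
        with pytest.raises(ValueError):
            smooth_imfa(make_series(np.ones(20)), span=0.0)

    def test_missing_weeks_stay_missing(self):
        values = np.full(30, 0.5)
        values[10] = np.nan
        out = smooth_imfa(make_series(values))
        assert np.isnan(out.values[10])
        assert np.isfinite(np.delete(out.values, 10)).all()


class TestMse:
    def test_identical_series_zero(self):
        s = make_series([0.3, 0.6, 0.9, 0.2])
        assert mse(s, s) == 0.0

    def test_hand_arithmetic(self):
        model = make_series([1.0, 2.0])
        observed = make_series([0.0, 0.0])
        assert mse(model, observed) == pytest.approx(2.5)

    def test_missing_weeks_excluded_pairwise(self):
        model = make_series([1.0, 2.0, 3.0])
        observed = make_series([0.0, np.nan, 0.0])
        assert mse(model, observed) == pytest.approx((1.0 + 9.0) / 2)

    def test_partial_overlap_uses_common_weeks(self):
        model = make_series([1.0, 2.0, 3.0], start="2008-01-07")
        observed = make_series([2.0, 3.0, 5.0], start="2008-01-14")
        # overlapping weeks: model[1:] vs observed[:2], both exactly equal
        assert mse(model, observed) == 0.0

    def test_disjoint_weeks_rejected(self):
        model = make_series([1.0, 2.0], start="2008-01-07")
        observed = make_series([1.0, 2.0], start="2010-01-07")
        with pytest.raises(ValueError):
            mse(model, observed)


@pytest.fixture(scope="module")
def noiseless_case():
    scenario = SyntheticScenario(K_true=2500.0, seed=99, n_years=2)
    return scenario, generate_trap_counts(scenario)


class TestFitK:
    def test_noiseless_self_consistency(self, noiseless_case):
        scenario, data = noiseless_case
        fit = fit_K(data.truth, data.forcing, scenario.life_history(),
                    scenario.trap_config, smooth=False)
        assert fit.K_hat == pytest.approx(2500.0, rel=1e-4)
        assert fit.mse < 1e-10
        assert fit.converged

    def test_scaling_and_brent_methods_agree(self, noiseless_case):
        scenario, data = noiseless_case
        kwargs = dict(params=scenario.life_history(), trap=scenario.trap_config,
                      smooth=True)
        a = fit_K(data.observed, data.forcing, kwargs["params"], kwargs["trap"],
                  smooth=True, method="scaling")
        b = fit_K(data.observed, data.forcing, kwargs["params"], kwargs["trap"],
                  smooth=True, method="brent")
        assert a.K_hat == pytest.approx(b.K_hat, rel=1e-3)
        assert a.mse == pytest.approx(b.mse, rel=1e-3)

    def test_deterministic(self, noiseless_case):
        scenario, data = noiseless_case
        fits = [
            fit_K(data.observed, data.forcing, scenario.life_history(),
                  scenario.trap_config)
            for _ in range(2)
        ]
        assert fits[0].K_hat == fits[1].K_hat
        assert fits[0].mse == fits[1].mse

    def test_optimum_is_a_local_minimum(self, noiseless_case):
        scenario, data = noiseless_case
        params, trap = scenario.life_history(), scenario.trap_config
        fit = fit_K(data.observed, data.forcing, params, trap)
        from aedes_capacity.calibration import _model_imfa, smooth_imfa as sm

        target = sm(data.observed)
        for factor in (0.9, 1.1):
            perturbed = mse(
                _model_imfa(params, trap, fit.K_hat * factor, data.forcing), target
            )
            assert fit.mse <= perturbed + 1e-12

    def test_bound_hit_flags_nonconvergence(self, noiseless_case):
        scenario, data = noiseless_case
        with pytest.warns(UserWarning, match="bounds"):
            fit = fit_K(data.truth, data.forcing, scenario.life_history(),
                        scenario.trap_config, bounds=(10.0, 100.0), smooth=False)
        assert not fit.converged
        assert fit.K_hat == 100.0

    def test_invalid_bounds_rejected(self, noiseless_case):
        scenario, data = noiseless_case
        with pytest.raises(ValueError):
            fit_K(data.truth, data.forcing, scenario.life_history(),
                  scenario.trap_config, bounds=(100.0, 10.0))


class TestFitAllAreas:
    def test_two_areas_preserve_K_ordering(self):
        items = []
        for area, (k, seed) in {"low": (1500.0, 1), "high": (3500.0, 2)}.items():
            sc = SyntheticScenario(K_true=k, seed=seed, n_years=2)
            d = generate_trap_counts(sc)
            items.append((area, d.observed, d.forcing, sc.trap_config))
        fits = fit_all_areas(items).set_index("area_id")
        assert fits.loc["low", "K_hat"] < fits.loc["high", "K_hat"]

    def test_single_area_matches_fit_K(self, noiseless_case):
        scenario, data = noiseless_case
        params = scenario.life_history()
        table = fit_all_areas(
            [("only", data.observed, data.forcing, scenario.trap_config)],
            params=params,
        )
        assert len(table) == 1
        direct = fit_K(data.observed, data.forcing, params, scenario.trap_config)
        assert table.loc[0, "K_hat"] == direct.K_hat

    def test_failures_recorded_not_raised(self, noiseless_case):
        scenario, data = noiseless_case
        bad_series = make_series(np.ones(6))  # too short to smooth
        table = fit_all_areas(
            [
                ("bad", bad_series, data.forcing, scenario.trap_config),
                ("good", data.observed, data.forcing, scenario.trap_config),
            ],
            params=scenario.life_history(),
        )
        assert table.set_index("area_id").loc["bad", "error"] != ""
        assert np.isfinite(table.set_index("area_id").loc["good", "K_hat"])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit_all_areas([])
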