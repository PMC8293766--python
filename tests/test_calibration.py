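"""Two-phase least-squares calibration: ceiling rule, evaporation fit,
decay fit, estimator protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from litmix import (
    BunnellMassCurve,
    DataError,
    EvaporationCurve,
    LitterParams,
    calibrate_litter,
    fit_decay,
    fit_evaporation,
    generate_single_litter_obs,
    initial_lwc_from_obs,
    simulate_single,
)
from litmix.synthetic import DesignSpec

from conftest import lwc_series, make_series

DAYS = (2, 7, 14, 28, 56, 84, 112)


def synthetic_lwc(e, lwc_max, days=DAYS):
    return lwc_series(days, [lwc_max * (1 - e) ** d for d in days])


class TestInitialLwc:
    @pytest.mark.parametrize(
        "first_day_values, expected",
        [
            ([21.56], 22),   # the documented rounding example
            ([3.0], 3),      # integers are fixed points of the ceiling
            ([2.01], 3),
            ([21.5, 21.62], 22),  # replicate mean, then ceiling
        ],
    )
    def test_ceiling_of_earliest_day_mean(self, first_day_values, expected):
        records = [(2, i + 1, "lwc", v) for i, v in enumerate(first_day_values)]
        records += [(7, 1, "lwc", 1.0)]
        assert initial_lwc_from_obs(make_series(records)) == expected

    def test_requires_lwc_records(self):
        series = make_series([(2, 1, "mass_fraction", 0.9),
                              (7, 1, "mass_fraction", 0.8)])
        with pytest.raises(DataError):
            initial_lwc_from_obs(series)


class TestFitEvaporation:
    @pytest.mark.parametrize("e_true", [0.001, 0.01, 0.1, 0.5])
    def test_noiseless_recovery_to_1e6(self, e_true):
        series = synthetic_lwc(e_true, lwc_max=3)
        fit = fit_evaporation(series, lwc_max=3)
        assert fit.values["e"] == pytest.approx(e_true, abs=1e-6)

    def test_recovers_typical_rate(self):
        series = synthetic_lwc(0.061, lwc_max=3)
        fit = fit_evaporation(series, lwc_max=3)
        assert fit.values["e"] == pytest.approx(0.061, abs=1e-6)

    def test_constant_series_gives_zero(self):
        series = lwc_series(DAYS, [5.0] * len(DAYS))
        fit = fit_evaporation(series, lwc_max=5)
        assert fit.values["e"] == pytest.approx(0.0, abs=1e-9)
        assert fit.bounds_active["e"] == "lower"

    def test_degenerate_single_day_rejected(self):
        # the container itself refuses a variable sampled on only one day
        with pytest.raises(DataError):
            make_series([(2, 1, "lwc", 3.0), (2, 2, "lwc", 2.9),
                         (7, 1, "mass_fraction", 0.9),
                         (14, 1, "mass_fraction", 0.8)])

    def test_pooled_replicates_match_balanced_means(self):
        """For a balanced design, fitting pooled replicates equals fitting
        the replicate means."""
        rng = np.random.default_rng(7)
        days = np.repeat(DAYS, 4)
        truth = 6.0 * (1 - 0.05) ** days
        values = np.clip(truth + rng.normal(0, 0.1, truth.size), 0.0, None)
        pooled = make_series([(int(d), i % 4 + 1, "lwc", float(v))
                              for i, (d, v) in enumerate(zip(days, values))])
        means = values.reshape(len(DAYS), 4).mean(axis=1)
        averaged = lwc_series(DAYS, means)
        fit_a = fit_evaporation(pooled, lwc_max=6)
        fit_b = fit_evaporation(averaged, lwc_max=6)
        assert fit_a.values["e"] == pytest.approx(fit_b.values["e"], abs=1e-7)


class TestFitDecay:
    def make_mass_series(self, params, days=DAYS):
        traj = simulate_single(params, horizon=max(days))
        return make_series([(d, 1, "mass_fraction",
                             float(traj.mass_fraction[d])) for d in days])

    def test_noiseless_recovery_kmax_tight(self):
        truth = LitterParams(name="t", lwc_max=3, k_max=0.006, e=0.061,
                             model_kind="bunnell", c=1.5, d=2.0)
        series = self.make_mass_series(truth)
        fit = fit_decay(series, lwc_max=3, e=0.061)
        assert fit.values["k_max"] == pytest.approx(0.006, abs=1e-4)
        # c and d are weakly identified; the fitted *curve* must match
        pred_params = fit.params
        pred = simulate_single(pred_params, horizon=112).mass_fraction
        true_curve = simulate_single(truth, horizon=112).mass_fraction
        np.testing.assert_allclose(pred[list(DAYS)], true_curve[list(DAYS)],
                                   atol=1e-6)

    def test_constant_mass_drives_kmax_to_lower_bound(self):
        series = make_series([(d, 1, "mass_fraction", 1.0) for d in DAYS])
        fit = fit_decay(series, lwc_max=3, e=0.061)
        assert fit.values["k_max"] < 1e-4
        assert fit.bounds_active["k_max"] == "lower"

    def test_c_d_respect_upper_bound(self, sphagnum, noiseless_design):
        obs = generate_single_litter_obs(sphagnum, noiseless_design)
        fit = fit_decay(obs, lwc_max=22, e=0.010)
        assert fit.values["c"] <= 22 + 1e-9
        assert fit.values["d"] <= 22 + 1e-9
        assert fit.bounds_active["c"] == "upper"
        assert fit.bounds_active["d"] == "upper"

    def test_objective_no_worse_than_truth(self, molinia, noiseless_design):
        design = DesignSpec(noise_sd_lwc=0.0, noise_sd_mass=0.01, seed=11)
        obs = generate_single_litter_obs(molinia, design)
        fit = fit_decay(obs, lwc_max=molinia.lwc_max, e=molinia.e)
        days, values = obs.xy("mass_fraction")
        truth_curve = simulate_single(molinia, horizon=int(days.max()))
        sse_truth = float(np.sum(
            (values - truth_curve.mass_fraction[days.astype(int)]) ** 2))
        assert fit.sse <= sse_truth + 1e-12

    def test_fit_is_reproducible(self, molinia):
        design = DesignSpec(noise_sd_mass=0.02, noise_sd_lwc=0.1, seed=5)
        obs = generate_single_litter_obs(molinia, design)
        fit1 = fit_decay(obs, lwc_max=3, e=0.061)
        fit2 = fit_decay(obs, lwc_max=3, e=0.061)
        assert fit1.values == fit2.values


class TestTwoPhase:
    def test_round_trip_on_noiseless_table2(self, table2, noiseless_design):
        """calibrate → simulate reproduces the generating trajectories."""
        for params in table2.values():
            obs = generate_single_litter_obs(params, noiseless_design)
            fit = calibrate_litter(obs)
            assert fit.params.lwc_max == params.lwc_max
            assert fit.params.e == pytest.approx(params.e, abs=1e-6)
            assert fit.params.k_max == pytest.approx(params.k_max, abs=1e-4)
            got = simulate_single(fit.params, horizon=112).mass_fraction
            want = simulate_single(params, horizon=112).mass_fraction
            np.testing.assert_allclose(got, want, atol=1e-6)

    @given(e_true=st.floats(0.005, 0.3))
    @settings(derandomize=True, deadline=None, max_examples=20)
    def test_evaporation_recovery_property(self, e_true):
        series = synthetic_lwc(e_true, lwc_max=10)
        fit = fit_evaporation(series, lwc_max=10)
        assert abs(fit.values["e"] - e_true) < 1e-6


class TestEstimatorProtocol:
    def test_clone_and_params_round_trip(self):
        est = EvaporationCurve(lwc_max=5, grid_size=500)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est2 = BunnellMassCurve(lwc_max=3, e=0.061)
        assert clone(est2).get_params()["e"] == 0.061
        est2.set_params(e=0.01)
        assert est2.e == 0.01

    def test_predict_requires_fit(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            EvaporationCurve(lwc_max=3).predict([[2.0]])

    def test_fit_predict_shapes(self):
        days = np.array(DAYS, dtype=float).reshape(-1, 1)
        y = 3 * (1 - 0.061) ** days.ravel()
        est = EvaporationCurve(lwc_max=3).fit(days, y)
        pred = est.predict(days)
        assert pred.shape == (len(DAYS),)
        np.testing.assert_allclose(pred, y, atol=1e-6)
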