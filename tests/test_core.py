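"""Single-litter kinetics: rate functions, evaporation, decay, stepping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litmix import (
    ConfigurationError,
    DomainError,
    LitterParams,
    LitterState,
    decay_step,
    evaporate,
    oxygen_availability,
    rate_bunnell,
    rate_moyano,
    simulate_single,
    step_single,
)

RTOL = 1e-9


class TestOxygenAvailability:
    @pytest.mark.parametrize(
        "lwc, lwc_max, expected",
        [
            (10, 10, 0.0),   # saturation: no oxygen
            (0, 10, 1.0),    # fully dry
            (5, 10, 0.5),
        ],
    )
    def test_values(self, lwc, lwc_max, expected):
        assert oxygen_availability(lwc, lwc_max) == pytest.approx(expected)

    @pytest.mark.parametrize("lwc", [-1.0, 10.5])
    def test_out_of_domain(self, lwc):
        with pytest.raises(DomainError):
            oxygen_availability(lwc, 10)


class TestRateFunctions:
    def test_moyano_zero_at_saturation_and_dry(self, moyano_params):
        assert rate_moyano(10.0, moyano_params) == 0.0
        assert rate_moyano(0.0, moyano_params) == 0.0

    def test_moyano_hand_value(self, moyano_params):
        # 0.01 * (5/10) * (0.5/(0.5+0.5))
        assert rate_moyano(5.0, moyano_params) == pytest.approx(0.0025, rel=RTOL)

    def test_bunnell_zero_when_dry_positive_at_saturation(self, bunnell_params):
        assert rate_bunnell(0.0, bunnell_params) == 0.0
        # 0.01 * (10/15) * (5/15): activity persists at saturation
        assert rate_bunnell(10.0, bunnell_params) == pytest.approx(
            0.01 * (10 / 15) * (5 / 15), rel=RTOL
        )
        assert rate_bunnell(10.0, bunnell_params) > 0

    def test_missing_constants_rejected_at_construction(self):
        with pytest.raises(ConfigurationError):
            LitterParams(name="x", lwc_max=10, k_max=0.01, e=0.1,
                         model_kind="bunnell", c=5)  # d missing
        with pytest.raises(ConfigurationError):
            LitterParams(name="x", lwc_max=10, k_max=0.01, e=0.1,
                         model_kind="moyano", a=5)  # b missing

    @given(
        c=st.floats(0.1, 50), d=st.floats(0.1, 50),
        lwc=st.floats(0.0, 100), lwc_max=st.floats(100, 200),
    )
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_bunnell_bounded_and_unimodal(self, c, d, lwc, lwc_max):
        """k is bounded by k_max with a single interior maximum at √(cd)."""
        params = LitterParams(name="h", lwc_max=lwc_max, k_max=0.01, e=0.0,
                              model_kind="bunnell", c=c, d=d)
        k = rate_bunnell(lwc, params)
        assert 0.0 <= k < params.k_max
        k_peak = rate_bunnell(math.sqrt(c * d), params)
        assert k <= k_peak * (1 + 1e-12)

    @given(lwc=st.floats(0, 10), a=st.floats(0.1, 20), b=st.floats(0.01, 5))
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_moyano_bounded(self, lwc, a, b):
        params = LitterParams(name="h", lwc_max=10, k_max=0.01, e=0.0,
                              model_kind="moyano", a=a, b=b)
        assert 0.0 <= rate_moyano(lwc, params) < params.k_max


class TestEvaporateAndDecay:
    def test_evaporate_one_step(self):
        assert evaporate(10.0, 0.1) == pytest.approx(9.0, rel=RTOL)
        assert evaporate(7.3, 0.0) == 7.3

    def test_evaporate_loop_matches_closed_form(self):
        lwc = 22.0
        for _ in range(10):
            lwc = evaporate(lwc, 0.010)
        assert lwc == pytest.approx(22.0 * 0.99**10, rel=RTOL)

    def test_evaporate_rejects_bad_rate(self):
        with pytest.raises(DomainError):
            evaporate(1.0, 1.5)
        with pytest.raises(DomainError):
            evaporate(1.0, -0.1)

    def test_decay_step(self):
        assert decay_step(1.0, 0.01) == pytest.approx(0.99, rel=RTOL)
        assert decay_step(0.5, 0.0) == 0.5

    def test_decay_loop_matches_closed_form(self):
        m = 1.0
        for _ in range(40):
            m = decay_step(m, 0.01)
        assert m == pytest.approx(0.99**40, rel=RTOL)

    def test_decay_rejects_bad_rate(self):
        with pytest.raises(DomainError):
            decay_step(1.0, 1.0)
        with pytest.raises(DomainError):
            decay_step(1.0, -0.01)


class TestStepAndSimulate:
    def test_step_order_evaporate_then_rate_then_decay(self, bunnell_params):
        state = LitterState(day=0, lwc=10.0, mass_fraction=1.0, k_current=0.0)
        nxt = step_single(state, bunnell_params)
        k_expected = 0.01 * (9 / 14) * (5 / 14)
        assert nxt.day == 1
        assert nxt.lwc == pytest.approx(9.0, rel=RTOL)
        assert nxt.k_current == pytest.approx(k_expected, rel=RTOL)
        assert nxt.mass_fraction == pytest.approx(1 - k_expected, rel=RTOL)

    def test_inert_litter_only_advances_the_clock(self):
        params = LitterParams(name="inert", lwc_max=10, k_max=0.0, e=0.0,
                              model_kind="bunnell", c=5, d=5)
        state = LitterState(day=3, lwc=4.0, mass_fraction=0.8, k_current=0.0)
        nxt = step_single(state, params)
        assert (nxt.day, nxt.lwc, nxt.mass_fraction) == (4, 4.0, 0.8)

    def test_trajectory_starts_at_saturation_and_day_zero(self, bunnell_params):
        traj = simulate_single(bunnell_params, horizon=5)
        assert traj.day[0] == 0 and traj.lwc[0] == bunnell_params.lwc_max
        assert traj.mass_fraction[0] == 1.0
        assert np.array_equal(traj.day, np.arange(6))

    def test_mass_non_increasing_and_lwc_non_increasing(self, bunnell_params):
        traj = simulate_single(bunnell_params, horizon=200)
        assert np.all(np.diff(traj.mass_fraction) <= 0)
        assert np.all(np.diff(traj.lwc) <= 0)

    @given(e=st.floats(0.0, 0.9), lwc_max=st.floats(0.5, 50))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_lwc_closed_form(self, e, lwc_max):
        params = LitterParams(name="h", lwc_max=lwc_max, k_max=0.01, e=e,
                              model_kind="bunnell", c=1, d=1)
        traj = simulate_single(params, horizon=60)
        expected = lwc_max * (1 - e) ** np.arange(61)
        np.testing.assert_allclose(traj.lwc, expected, rtol=1e-9, atol=1e-300)

    def test_constant_lwc_gives_closed_form_mass(self, bunnell_params):
        params = bunnell_params.with_updates(e=0.0)
        traj = simulate_single(params, horizon=40)
        k = rate_bunnell(params.lwc_max, params)
        np.testing.assert_allclose(
            traj.mass_fraction, (1 - k) ** np.arange(41), rtol=1e-9
        )

    def test_dry_litter_rate_declines_toward_zero(self, bunnell_params):
        """A fast-evaporating litter's decay rate collapses as it dries."""
        traj = simulate_single(bunnell_params, horizon=80)  # e = 0.1
        k = traj.k[1:]
        # k rises briefly while drying toward the moisture optimum (√(cd)),
        # then declines monotonically toward zero as the litter desiccates
        peak = int(np.argmax(k))
        assert peak < 10
        assert np.all(np.diff(k[peak:]) <= 1e-15)
        assert k[-1] < 1e-4 < k[0]

    def test_trajectory_frame_round_trip(self, bunnell_params):
        traj = simulate_single(bunnell_params, horizon=4)
        frame = traj.to_frame()
        assert list(frame.columns) == ["day", "litter", "lwc", "k",
                                       "mass_fraction"]
        assert (frame["litter"] == "demo").all()
        state = traj.state(2)
        assert state.lwc == frame.loc[2, "lwc"]
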