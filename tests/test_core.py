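"""Filter recursion: measurement model, single updates, full runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nskf import (
    ModelParams,
    StateSpaceParams,
    build_schedule,
    kalman_step,
    measurement_variance,
    riccati_fixed_point,
    run_filter,
    state_space_run,
)

finite_means = st.floats(-1.0, 1.0)
pos_vars = st.floats(1e-8, 1.0)


class TestMeasurementVariance:
    @pytest.mark.parametrize(
        "base,delta,delay,expected",
        [
            (0.0010, 1.7e-4, 0.0, 0.0010),  # no delay: baseline noise only
            (0.0010, 1.7e-4, 135.0, 0.02395),  # MC growth at full perturbation
            (0.0015, 0.0, 100.0, 0.0015),  # zero growth: stationary filter
        ],
    )
    def test_linear_growth(self, base, delta, delay, expected):
        p = ModelParams(base_meas_var=base, delta_meas_var=delta)
        assert measurement_variance(p, delay) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_in_delay(self, mc_params):
        delays = np.arange(0, 136)
        mv = [measurement_variance(mc_params, d) for d in delays]
        assert np.all(np.diff(mv) > 0)

    def test_negative_delay_rejected(self, mc_params):
        with pytest.raises(ValueError, match="delay"):
            measurement_variance(mc_params, -1.0)


class TestKalmanStep:
    def test_equal_variances_split_the_difference(self):
        gain, post_mean, _ = kalman_step(0.0, 0.04, 0.1, 0.04)
        assert gain == pytest.approx(0.5)
        assert post_mean == pytest.approx(0.05)

    def test_uninformative_measurement_keeps_prior(self):
        gain, post_mean, post_var = kalman_step(0.2, 1e-4, 5.0, 1e12)
        assert gain == pytest.approx(0.0, abs=1e-10)
        assert post_mean == pytest.approx(0.2, abs=1e-10)
        assert post_var == pytest.approx(1e-4, rel=1e-6)

    def test_hand_computed_update(self):
        # prior (0, 0.25) against a 135 ms measurement with the MC
        # full-delay measurement variance
        gain, post_mean, post_var = kalman_step(0.0, 0.25, 0.135, 0.02395)
        assert gain == pytest.approx(0.25 / 0.27395, rel=1e-9)
        assert post_mean == pytest.approx(0.135 * 0.25 / 0.27395, rel=1e-9)
        assert post_var == pytest.approx((1 - 0.25 / 0.27395) * 0.25, rel=1e-9)
        assert gain == pytest.approx(0.912575, abs=5e-6)
        assert post_mean == pytest.approx(0.123198, abs=5e-6)
        assert post_var == pytest.approx(0.0218562, abs=5e-7)

    @pytest.mark.parametrize("prior_var,meas_var", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_nonpositive_variances_rejected(self, prior_var, meas_var):
        with pytest.raises(ValueError):
            kalman_step(0.0, prior_var, 0.0, meas_var)

    @settings(deadline=None, derandomize=True)
    @given(prior_mean=finite_means, prior_var=pos_vars, meas=finite_means, meas_var=pos_vars)
    def test_update_invariants(self, prior_mean, prior_var, meas, meas_var):
        """Gain in (0,1); variance never grows; posterior mean is a convex
        combination of prior mean and measurement."""
        gain, post_mean, post_var = kalman_step(prior_mean, prior_var, meas, meas_var)
        assert 0.0 < gain < 1.0
        assert post_var <= prior_var
        lo, hi = min(prior_mean, meas), max(prior_mean, meas)
        assert lo - 1e-12 <= post_mean <= hi + 1e-12


class TestRunFilter:
    def test_zero_input_stays_at_zero_and_variance_contracts(self, mc_params):
        trace = run_filter(mc_params, [0.0] * 200)
        assert np.allclose(trace.post_means, 0.0)
        assert np.all(np.diff(trace.post_vars[:50]) < 0)
        vstar = riccati_fixed_point(mc_params.process_var, mc_params.base_meas_var)
        assert trace.prior_vars[-1] == pytest.approx(vstar, abs=1e-12)

    def test_chaining_identities(self, mc_params, incremental_schedule):
        """Prior of trial t equals posterior of t−1; prior variance adds the
        process variance."""
        trace = run_filter(mc_params, incremental_schedule)
        for prev, cur in zip(trace.steps, trace.steps[1:]):
            assert cur.prior_mean == prev.post_mean
            assert cur.prior_var == pytest.approx(
                prev.post_var + mc_params.process_var, rel=1e-14
            )

    def test_zero_growth_reduces_to_stationary_filter(self, mc_params, incremental_schedule):
        """With zero variance growth the delay ramp changes measurements but
        not their variance: every meas_var equals the baseline value."""
        trace = run_filter(mc_params.with_delta(0.0), incremental_schedule)
        assert np.allclose(trace.meas_vars, mc_params.base_meas_var)

    def test_gain_decreases_with_delay(self, mc_params):
        """All else equal, a larger imposed delay makes the first-trial
        measurement less reliable and the gain smaller."""
        gains = [run_filter(mc_params, [d]).gains[0] for d in (0, 10, 50, 135)]
        assert np.all(np.diff(gains) < 0)

    def test_empty_schedule_rejected(self, mc_params):
        with pytest.raises(ValueError, match="at least one"):
            run_filter(mc_params, [])

    def test_phase_labels_carried_through(self, mc_params, incremental_schedule):
        trace = run_filter(mc_params, incremental_schedule)
        assert trace.phase_labels == list(incremental_schedule.phase_labels)

    def test_trace_dataframe_shape(self, mc_params, incremental_schedule):
        df = run_filter(mc_params, incremental_schedule).to_dataframe()
        assert len(df) == 270
        assert {"trial", "gain", "prior_mean_s", "post_var_s2", "phase"} <= set(df.columns)


class TestGainAsymptotics:
    def test_skf_gain_asymptotes_nskf_gain_keeps_declining(self, mc_params, incremental_schedule):
        """Under the incremental ramp the stationary filter's gain settles to
        a constant while the delay-dependent filter's gain keeps falling."""
        skf = run_filter(mc_params.with_delta(0.0), incremental_schedule)
        nskf_ = run_filter(mc_params, incremental_schedule)
        adapt = slice(135, 270)
        assert np.ptp(skf.gains[-50:]) < 1e-6
        assert np.all(np.diff(nskf_.gains[adapt]) < 0)


class TestStateSpace:
    def test_no_learning_stays_at_zero(self):
        x = state_space_run(StateSpaceParams(1.0, 0.0), [1.0, -2.0, 3.0])
        assert np.allclose(x, 0.0)

    def test_pure_learning_shifts_errors(self):
        e = [0.5, -0.25, 1.0]
        x = state_space_run(StateSpaceParams(0.0, 1.0), e)
        assert np.allclose(x, e)

    def test_constant_error_converges_to_geometric_limit(self):
        """x_t → B/(1−A) under constant unit error (geometric series)."""
        x = state_space_run(StateSpaceParams(0.9, 0.1), np.ones(500))
        assert x[-1] == pytest.approx(0.1 / (1 - 0.9), rel=1e-4)

    @pytest.mark.parametrize("a,b", [(-0.1, 0.5), (1.1, 0.5), (0.5, -0.1), (0.5, 1.5)])
    def test_out_of_range_parameters_rejected(self, a, b):
        with pytest.raises(ValueError):
            StateSpaceParams(a, b)


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"var0_prior": 0.0},
            {"process_var": -1e-6},
            {"base_meas_var": 0.0},
            {"delta_meas_var": -1e-5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_with_delta_copies(self, mc_params):
        p2 = mc_params.with_delta(0.0)
        assert p2.delta_meas_var == 0.0
        assert p2.base_meas_var == mc_params.base_meas_var
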