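"""Kinetic parameter extraction: thresholds, censoring, slopes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tauseed import (
    AssayConfig,
    compute_fmax,
    compute_lag_time,
    compute_time_to_fmax,
    compute_vmax,
    restrict_to_cutoff,
    summarize_sample,
    summarize_well,
)

SMALL = AssayConfig(baseline_n_reads=4, slope_window=2)


class TestRestrictToCutoff:
    def test_drops_reads_after_cutoff(self, logistic_curve):
        curve = logistic_curve(duration_h=60.0).curve
        out = restrict_to_cutoff(curve, AssayConfig())
        assert out.times_h[-1] <= 52.0
        assert curve.times_h[-1] == 60.0

    def test_identity_when_within_cutoff(self, make_curve):
        curve = make_curve([0, 1, 2, 3], [1, 2, 3, 4])
        out = restrict_to_cutoff(curve, AssayConfig())
        assert out is curve

    def test_empty_window_errors(self, make_curve):
        curve = make_curve([0.25, 0.5, 0.75], [1, 2, 3])
        with pytest.raises(ValueError, match="cutoff"):
            restrict_to_cutoff(curve, AssayConfig(cutoff_h=0.1))


class TestFmax:
    def test_list_maximum(self, make_curve):
        curve = make_curve([0, 1, 2, 3], [100, 105, 200, 180])
        assert compute_fmax(curve, SMALL) == 200

    def test_constant(self, make_curve):
        curve = make_curve([0, 1, 2, 3], [100, 100, 100, 100])
        assert compute_fmax(curve, SMALL) == 100

    def test_peak_after_cutoff_excluded(self, make_curve):
        # oracle: brute-force max over the reads at or before 52 h
        times = np.arange(0, 60.5, 0.5)
        fluor = np.where(times < 54, 100.0, 900.0)
        fluor[times == 50.0] = 400.0
        curve = make_curve(times, fluor)
        retained = fluor[times <= 52.0]
        assert compute_fmax(curve, AssayConfig()) == retained.max() == 400.0


class TestLagTime:
    def test_zero_sd_threshold_triggers_on_any_rise(self, make_curve):
        times = [0, 1, 2, 3, 4, 5, 6]
        fluor = [100, 100, 100, 100, 100, 101, 300]
        lag, censored = compute_lag_time(make_curve(times, fluor), SMALL)
        assert (lag, censored) == (5.0, False)

    def test_hand_computed_sample_sd_threshold(self, make_curve):
        # baseline [100, 102, 98, 100]: mean 100, sample SD 1.632993,
        # threshold 108.1650; the first strictly greater read is at 6.25 h
        times = np.arange(0, 8.25, 0.25)
        fluor = np.full(times.size, 100.0)
        fluor[1], fluor[2] = 102.0, 98.0
        fluor[(times >= 5.0) & (times < 6.25)] = 108.0
        fluor[times >= 6.25] = 120.0
        lag, censored = compute_lag_time(make_curve(times, fluor), SMALL)
        assert not censored
        assert lag == 6.25

    def test_flat_curve_censored_at_cutoff(self, make_curve):
        times = np.arange(0, 60.25, 0.25)
        curve = make_curve(times, np.full(times.size, 100.0))
        lag, censored = compute_lag_time(curve, AssayConfig())
        assert censored
        assert lag == 52.0

    def test_baseline_window_longer_than_curve_errors(self, make_curve):
        curve = make_curve([0, 1, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="baseline"):
            compute_lag_time(curve, AssayConfig(baseline_n_reads=10))

    def test_agrees_with_analytic_crossing(self, logistic_curve):
        """Noise-free oracle: the first read above the measured threshold
        sits within one read interval of the closed-form crossing time."""
        from tauseed.kinetics import baseline_threshold

        sim = logistic_curve(amplitude=2500, rate_k=0.7, t_half=18.0)
        config = AssayConfig()
        theta = baseline_threshold(sim.curve, config)
        lag, censored = compute_lag_time(sim.curve, config)
        assert not censored
        assert abs(lag - sim.analytic_lag(theta)) <= 0.25

    @given(n_sd_lo=st.floats(0.5, 4.9), n_sd_hi=st.floats(5.0, 12.0))
    def test_lag_monotone_in_n_sd(self, n_sd_lo, n_sd_hi):
        from tauseed.synthetic import AggregationKineticsParams, simulate_tht_curve

        sim = simulate_tht_curve(
            AggregationKineticsParams(
                f0=100, amplitude=2000, rate_k=0.6, t_half=20,
                noise_sd=30, rng_seed=7,
            )
        )
        lo, _ = compute_lag_time(sim.curve, AssayConfig(n_sd=n_sd_lo))
        hi, _ = compute_lag_time(sim.curve, AssayConfig(n_sd=n_sd_hi))
        assert hi >= lo


class TestTimeToFmax:
    def test_first_attainment(self, make_curve):
        curve = make_curve([0, 1, 2, 3, 4], [0, 10, 30, 35, 35])
        t, censored = compute_time_to_fmax(curve, SMALL)
        assert (t, censored) == (3.0, False)

    def test_strictly_increasing_censors_at_cutoff(self, make_curve):
        times = np.arange(0, 60.25, 0.25)
        curve = make_curve(times, times * 10.0)
        t, censored = compute_time_to_fmax(curve, AssayConfig())
        assert censored
        assert t == 52.0

    def test_tie_breaks_to_first_maximum(self, make_curve):
        times = np.arange(0, 30.0, 1.0)
        fluor = np.zeros(times.size)
        fluor[times == 10] = 50.0
        fluor[times == 20] = 50.0
        t, _ = compute_time_to_fmax(make_curve(times, fluor), SMALL)
        assert t == 10.0


class TestVmax:
    def test_finite_differences_with_window_two(self, make_curve):
        curve = make_curve([0, 1, 2, 3], [0, 10, 30, 35])
        assert compute_vmax(curve, SMALL) == 20.0

    def test_constant_curve_zero_slope(self, make_curve):
        curve = make_curve([0, 1, 2, 3], [5, 5, 5, 5])
        assert compute_vmax(curve, SMALL) == 0.0

    @pytest.mark.parametrize("slope_window", [2, 5])
    def test_dense_logistic_matches_closed_form(self, logistic_curve, slope_window):
        # maximum derivative of a logistic is rate_k * amplitude / 4
        sim = logistic_curve(
            amplitude=2000, rate_k=0.8, t_half=20, read_interval_h=0.02,
            duration_h=40,
        )
        vmax = compute_vmax(sim.curve, AssayConfig(slope_window=slope_window))
        assert vmax == pytest.approx(0.8 * 2000 / 4, rel=0.02)

    def test_too_few_points_errors(self, make_curve):
        curve = make_curve([0, 1], [0, 1])
        with pytest.raises(ValueError, match="reads"):
            compute_vmax(curve, SMALL)


class TestSummaries:
    def test_identical_replicates_mean_equals_single_well(self, logistic_curve):
        from dataclasses import replace

        curve = logistic_curve().curve
        wells = [replace(curve, well_id=w) for w in ("A1", "A2", "A3")]
        mean, table = summarize_sample(wells, AssayConfig())
        single = summarize_well(curve, AssayConfig())
        assert len(table) == 3
        assert mean.lag_h == single.lag_h
        assert mean.fmax == single.fmax

    def test_censored_wells_enter_mean_at_cutoff(self, make_curve):
        times = np.arange(0, 60.25, 0.25)

        def stepped(lag):
            f = np.full(times.size, 100.0)
            if lag is not None:
                f[times >= lag] = 3000.0
            return f

        curves = [
            make_curve(times, stepped(10.0), well_id="A1"),
            make_curve(times, stepped(12.0), well_id="A2"),
            make_curve(times, stepped(None), well_id="A3"),
        ]
        mean, table = summarize_sample(curves, AssayConfig())
        assert table["lag_censored"].tolist() == [False, False, True]
        assert mean.lag_h == pytest.approx((10 + 12 + 52) / 3)

    def test_empty_and_mixed_sample_inputs_error(self, make_curve):
        with pytest.raises(ValueError):
            summarize_sample([], AssayConfig())
        a = make_curve([0, 1, 2, 3, 4], [1, 2, 3, 4, 5], sample_id="s1")
        b = make_curve([0, 1, 2, 3, 4], [1, 2, 3, 4, 5], sample_id="s2")
        with pytest.raises(ValueError, match="several samples"):
            summarize_sample([a, b], SMALL)


@given(
    rate_k=st.floats(0.3, 1.2),
    t_half=st.floats(12.0, 40.0),
    amplitude=st.floats(500.0, 4000.0),
)
def test_lag_precedes_time_to_fmax_on_monotone_curves(rate_k, t_half, amplitude, logistic_curve):
    """For noise-free sigmoidal (monotone non-decreasing) curves the
    threshold crossing cannot come after the maximum, and no time parameter
    exceeds the cut-off; censored values equal the cut-off exactly."""
    sim = logistic_curve(amplitude=amplitude, rate_k=rate_k, t_half=t_half)
    config = AssayConfig()
    s = summarize_well(sim.curve, config)
    assert s.lag_h <= s.t_fmax_h
    assert s.lag_h <= config.cutoff_h and s.t_fmax_h <= config.cutoff_h
    if s.lag_censored:
        assert s.lag_h == config.cutoff_h
    if s.t_fmax_censored:
        assert s.t_fmax_h == config.cutoff_h
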