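"""Generators: curve model, plates, histology fields, biosensor fields."""

import io
import math

import numpy as np
import pytest

from tauseed import (
    AggregationKineticsParams,
    GroupName,
    SyntheticImageSpec,
    default_presets,
    cohort_presets,
    logistic_crossing_time,
    simulate_cohort_measurements,
    simulate_fret_field,
    simulate_histology_image,
    simulate_plate,
    simulate_tht_curve,
)
from tauseed.io import write_plate_csv


class TestThTCurveModel:
    def test_logistic_midpoint_is_half_rise(self):
        sim = simulate_tht_curve(
            AggregationKineticsParams(f0=100, amplitude=900, rate_k=1.0, t_half=10)
        )
        at_mid = sim.curve.fluorescence_au[sim.curve.times_h == 10.0]
        assert at_mid == pytest.approx(550.0)

    def test_closed_form_crossing_matches_dense_grid_search(self):
        # independent oracle: first time on a very fine grid above threshold
        # solving f0 + A/(1+exp(-k(t-t_half))) = theta gives
        # t = t_half - ln(A/(theta-f0) - 1)/k = 10 - ln(8) here
        f0, amp, k, t_half, theta = 100.0, 900.0, 1.0, 10.0, 200.0
        analytic = logistic_crossing_time(f0, amp, k, t_half, theta)
        assert analytic == pytest.approx(10 - math.log(8), abs=1e-12)
        t = np.arange(0, 30, 1e-4)
        f = f0 + amp / (1 + np.exp(-k * (t - t_half)))
        grid = t[np.argmax(f > theta)]
        assert analytic == pytest.approx(grid, abs=2e-4)

    def test_threshold_outside_range_never_crosses(self):
        assert logistic_crossing_time(100, 900, 1.0, 10.0, 100.0) == math.inf
        assert logistic_crossing_time(100, 900, 1.0, 10.0, 1001.0) == math.inf

    def test_zero_amplitude_gives_flat_noisy_baseline(self):
        sim = simulate_tht_curve(
            AggregationKineticsParams(
                f0=100, amplitude=0, rate_k=1.0, t_half=10, noise_sd=5, rng_seed=3
            )
        )
        f = sim.curve.fluorescence_au
        assert abs(f.mean() - 100) < 2
        assert f.std() == pytest.approx(5, rel=0.3)

    def test_read_grid(self):
        sim = simulate_tht_curve(
            AggregationKineticsParams(f0=0, amplitude=1, rate_k=1, t_half=1)
        )
        assert sim.curve.times_h[0] == 0.0
        assert sim.curve.times_h[-1] == 60.0
        assert np.allclose(np.diff(sim.curve.times_h), 0.25)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AggregationKineticsParams(f0=0, amplitude=-1, rate_k=1, t_half=1)
        with pytest.raises(ValueError):
            AggregationKineticsParams(f0=0, amplitude=1, rate_k=0, t_half=1)


class TestPlate:
    def test_cohort_layout_and_replicates(self):
        plate, truth = simulate_plate(default_presets(), rng_seed=0)
        # 6 + 5 + 5 samples in triplicate plus two controls in triplicate
        assert plate["well"].nunique() == 16 * 3 + 6
        assert truth.groupby("sample_id")["well"].count().eq(3).all()

    def test_neg_control_ground_truth_never_crosses(self):
        _, truth = simulate_plate(default_presets(), rng_seed=1)
        neg = truth[truth["group"] == GroupName.NEG_CONTROL.value]
        assert neg["true_lag_never"].all()
        pos = truth[truth["group"] == GroupName.POS_CONTROL.value]
        assert (~pos["true_lag_never"]).all()

    def test_same_seed_byte_identical_csv(self):
        bufs = []
        for _ in range(2):
            plate, _ = simulate_plate(default_presets(), rng_seed=42)
            buf = io.StringIO()
            write_plate_csv(plate, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_capacity_error_above_96_wells(self):
        presets = [p for p in default_presets()]
        too_many = [presets[0]] * 6  # 6 * 6 samples * 3 replicates = 108 wells
        with pytest.raises(ValueError, match="96"):
            simulate_plate(too_many, rng_seed=0)


class TestHistologyImages:
    def test_pure_noise_image_has_empty_truth(self):
        spec = SyntheticImageSpec(n_diffuse=0, n_perikaryal=0, rng_seed=0)
        image, objects = simulate_histology_image(spec)
        assert objects == []
        assert image.dtype == np.uint16
        assert image.max() < spec.foreground_intensity

    def test_diffuse_pixel_areas_within_derived_bounds(self):
        # 1.5-3.5 um^2 at 0.25 um/px (0.0625 um^2/px) is 24-56 pixels
        spec = SyntheticImageSpec(n_diffuse=30, n_perikaryal=0, rng_seed=5)
        _, objects = simulate_histology_image(spec)
        assert len(objects) == 30
        for obj in objects:
            assert 24 <= obj["pixel_count"] <= 56
            assert 1.5 <= obj["area_um2"] <= 3.5

    def test_rasterization_fidelity_within_one_pixel_area(self):
        spec = SyntheticImageSpec(n_diffuse=40, n_perikaryal=8, rng_seed=9)
        _, objects = simulate_histology_image(spec)
        pa = spec.pixel_size_um**2
        for obj in objects:
            assert abs(obj["area_um2"] - obj["requested_area_um2"]) <= pa

    def test_same_seed_identical_image(self):
        spec = SyntheticImageSpec(n_diffuse=20, n_perikaryal=3, rng_seed=11)
        a, _ = simulate_histology_image(spec)
        b, _ = simulate_histology_image(spec)
        assert np.array_equal(a, b)

    def test_overcrowded_field_errors(self):
        spec = SyntheticImageSpec(
            n_diffuse=0, n_perikaryal=400, width_px=128, height_px=128, rng_seed=0
        )
        with pytest.raises(RuntimeError, match="density"):
            simulate_histology_image(spec)


class TestFretFields:
    def test_zero_fraction_means_no_puncta(self):
        field, truth = simulate_fret_field(30, 0.0, rng_seed=0)
        assert truth["n_with_inclusions"] == 0
        assert field[1].max() < 12000

    def test_exact_flagged_count(self):
        _, truth = simulate_fret_field(50, 0.06, rng_seed=1)
        assert truth["n_with_inclusions"] == 3
        assert sum(c["has_inclusion"] for c in truth["cells"]) == 3

    def test_full_fraction_flags_every_cell(self):
        _, truth = simulate_fret_field(25, 1.0, rng_seed=2)
        assert all(c["has_inclusion"] for c in truth["cells"])

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_fret_field(10, 1.5, rng_seed=0)


class TestCohortMeasurements:
    def test_sheet_shape_and_ground_truth(self):
        sheet = simulate_cohort_measurements(cohort_presets(), rng_seed=0)
        assert len(sheet) == 16
        assert (sheet["pla_diffuse_mean"] >= 0).all()
        assert set(sheet["true_group"]) == {
            "DOUBLE_NEGATIVE", "INTERMEDIATE", "DOUBLE_POSITIVE",
        }
        assert (sheet.loc[sheet["true_group"] == "DOUBLE_NEGATIVE", "braak_stage"] == "0").all()
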