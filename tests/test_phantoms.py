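import numpy as np
import pytest

from padenoise.phantoms import (
    BleachModel,
    PhantomSpec,
    default_phantom_suite,
    make_gaussian_pairs,
    make_paired_dataset,
    make_phantom,
    simulate_point_exposure,
    simulate_raster_scan,
    suggest_roi,
    write_paired_dataset,
)


class TestMakePhantom:
    def test_tube_spans_declared_range_exactly(self):
        spec = PhantomSpec("tube_cross_section", radius=10, thickness=3,
                           amplitude=1.0, background_level=0.0)
        img = make_phantom(spec, (64, 64), seed=0)
        assert img.pixels.max() == 1.0
        assert img.pixels.min() == 0.0

    def test_deterministic_given_spec_and_seed(self):
        spec = PhantomSpec("vessel_tree", thickness=4)
        a = make_phantom(spec, (64, 64), seed=7)
        b = make_phantom(spec, (64, 64), seed=7)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        c = make_phantom(spec, (64, 64), seed=8)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_tube_renders_top_and_bottom_arcs(self):
        spec = PhantomSpec("tube_cross_section", radius=12, thickness=3)
        px = make_phantom(spec, (64, 64), seed=0).pixels
        # bright at the poles of the circle, dark at the lateral walls
        assert px[32 - 12, 32] > 0.9 and px[32 + 12, 32] > 0.9
        assert px[32, 32 - 12] < 0.1 and px[32, 32 + 12] < 0.1

    @pytest.mark.parametrize("orientation", [0.0, 30.0, -45.0])
    def test_fiber_stroke_area_matches_rasterization_oracle(self, orientation):
        t = 3.0
        spec = PhantomSpec("fiber", thickness=t, orientation_deg=orientation)
        px = make_phantom(spec, (128, 128), seed=0).pixels
        measured = int((px > 0.5).sum())
        # oracle: count grid points within t/2 of the analytic center line
        theta = np.deg2rad(orientation)
        nr, nc = np.cos(theta), -np.sin(theta)
        rr, cc = np.mgrid[0:128, 0:128].astype(float)
        d = np.abs((rr - 64) * nr + (cc - 64) * nc)
        expected = int((d < t / 2).sum())
        assert measured == pytest.approx(expected, rel=0.10)

    def test_geometry_outside_image_rejected(self):
        spec = PhantomSpec("tube_cross_section", radius=40, thickness=3)
        with pytest.raises(ValueError):
            make_phantom(spec, (64, 64), seed=0)
        with pytest.raises(ValueError):
            make_phantom(PhantomSpec("fiber"), (16, 16), seed=0)  # below 32x32

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec("blob")
        with pytest.raises(ValueError):
            PhantomSpec("fiber", amplitude=0.2, background_level=0.5)


class TestPairedDataset:
    @pytest.mark.parametrize("F", [1, 16, 128, 25600])
    def test_residual_noise_scales_as_inverse_sqrt_frames(self, F):
        sigma = 0.5
        pairs = make_paired_dataset(default_phantom_suite((64, 64)), 30,
                                    F_in=F, F_label=F * 100,
                                    per_frame_noise_sigma=sigma, seed=3)
        resid = np.concatenate([(p.input.pixels - p.target.pixels).ravel() for p in pairs])
        assert resid.size >= 1e5
        expected = sigma * np.sqrt(1.0 / F + 1.0 / (F * 100))
        assert np.std(resid) == pytest.approx(expected, rel=0.05)

    def test_seed_reproducibility_and_order_independence(self):
        specs = default_phantom_suite((64, 64))
        a = make_paired_dataset(specs, 6, seed=5)
        b = make_paired_dataset(specs, 6, seed=5)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.input.pixels, pb.input.pixels)
        # sample i is a pure function of (seed, i): a longer dataset starts
        # with the shorter one
        longer = make_paired_dataset(specs, 8, seed=5)
        np.testing.assert_array_equal(a[2].input.pixels, longer[2].input.pixels)

    def test_validation_errors(self):
        specs = default_phantom_suite((64, 64))
        with pytest.raises(ValueError):
            make_paired_dataset(specs, 0, seed=0)
        with pytest.raises(ValueError):
            make_paired_dataset(specs, 2, F_in=100, F_label=100, seed=0)

    def test_gaussian_benchmark_pairs_have_clean_targets(self):
        pairs = make_gaussian_pairs(default_phantom_suite((64, 64)), 4, sigma=0.1, seed=0)
        resid = pairs[0].input.pixels - pairs[0].target.pixels
        assert np.std(resid) == pytest.approx(0.1, rel=0.1)
        assert pairs[0].target.pixels.max() == 1.0


class TestBleaching:
    def test_point_exposure_closed_form(self):
        seq = simulate_point_exposure(BleachModel(beta=0.001), 430)
        assert seq[0] == 1.0
        assert seq[-1] == pytest.approx(0.999**430)
        assert seq[-1] == pytest.approx(0.650, abs=0.001)  # ~35% drop
        assert np.all(np.diff(seq) < 0)

    def test_point_exposure_no_bleach_is_constant(self):
        seq = simulate_point_exposure(BleachModel(beta=0.0), 100)
        np.testing.assert_array_equal(seq, np.ones(101))

    def test_invalid_bleach_model_rejected(self):
        with pytest.raises(ValueError):
            BleachModel(beta=1.0)
        with pytest.raises(ValueError):
            BleachModel(beta=-0.1)

    def test_raster_scan_matches_pulse_by_pulse_scalar_oracle(self):
        spec = PhantomSpec("tube_cross_section", radius=10, thickness=3)
        bleach = BleachModel(beta=0.01, beam_sigma_mm=0.2, step_mm=0.1)
        series = simulate_raster_scan(spec, bleach, n_positions=6, pulses_per_position=30,
                                      noise_sigma_per_pulse=0.0, seed=1, shape=(64, 64))
        peak0 = make_phantom(spec, (64, 64), seed=1).pixels.max()
        pos = series.positions_mm
        conc = np.ones(6)
        expected = np.empty(6)
        for k in range(6):
            acc = 0.0
            for _ in range(30):
                acc += conc[k]
                conc = conc * (1 - bleach.beta * np.exp(-2 * ((pos - pos[k]) / bleach.beam_sigma_mm) ** 2))
            expected[k] = acc / 30 * peak0
        np.testing.assert_allclose(series.peak_amplitudes, expected, rtol=1e-10)

    def test_no_bleach_scan_has_constant_amplitudes(self):
        spec = PhantomSpec("tube_cross_section", radius=10, thickness=3)
        series = simulate_raster_scan(spec, BleachModel(beta=0.0), 5, 1, 0.0, seed=0)
        np.testing.assert_allclose(series.peak_amplitudes,
                                   series.peak_amplitudes[0] * np.ones(5), rtol=1e-12)

    def test_narrow_beam_single_pulse_sees_unbleached_dye(self):
        spec = PhantomSpec("tube_cross_section", radius=10, thickness=3)
        bleach = BleachModel(beta=0.05, beam_sigma_mm=1e-4, step_mm=0.1)
        series = simulate_raster_scan(spec, bleach, 8, 1, 0.0, seed=0)
        # no beam overlap: every position's first pulse images full concentration
        np.testing.assert_allclose(series.peak_amplitudes,
                                   series.peak_amplitudes[0] * np.ones(8), rtol=1e-6)

    @pytest.mark.parametrize("pulses", [(1, 5), (5, 30)])
    def test_final_position_bleaching_grows_with_pulses_per_position(self, pulses):
        spec = PhantomSpec("tube_cross_section", radius=10, thickness=3)
        bleach = BleachModel(beta=0.01, beam_sigma_mm=0.2, step_mm=0.1)
        lo, hi = pulses
        def final_drop(n):
            s = simulate_raster_scan(spec, bleach, 10, n, 0.0, seed=0)
            return 1.0 - s.peak_amplitudes[-1] / s.peak_amplitudes[0]
        assert final_drop(hi) >= final_drop(lo)

    def test_raster_scan_is_reproducible(self):
        spec = PhantomSpec("fiber", thickness=3)
        a = simulate_raster_scan(spec, BleachModel(), 4, 2, 0.1, seed=9)
        b = simulate_raster_scan(spec, BleachModel(), 4, 2, 0.1, seed=9)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa.pixels, fb.pixels)


def test_suggest_roi_boxes_hug_structure_and_background(gradient_image):
    spec = PhantomSpec("tube_cross_section", radius=10, thickness=3)
    clean = make_phantom(spec, (64, 64), seed=0)
    roi = suggest_roi(clean)
    assert roi.signal(clean).mean() > 5 * clean.pixels.mean()
    assert roi.background(clean).max() < 0.05


def test_write_paired_dataset_writes_tiffs_and_manifest(tmp_path):
    pairs = make_paired_dataset(default_phantom_suite((64, 64)), 3, seed=0)
    write_paired_dataset(tmp_path / "ds", pairs)
    files = sorted(p.name for p in (tmp_path / "ds").iterdir())
    assert "manifest.yaml" in files
    assert sum(f.endswith("_input.tif") for f in files) == 3
    assert sum(f.endswith("_target.tif") for f in files) == 3
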