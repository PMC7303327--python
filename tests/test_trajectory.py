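"""Trajectory metrics: lateral reconstruction, virtual line, XCoB, RP/LP, MLW."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vestigait.io import UniformSeries
from vestigait.trajectory import (
    DeviationSeries,
    compute_mlw,
    compute_rp_lp,
    compute_xcob,
    reconstruct_lateral,
    subtract_virtual_line,
)

RATE = 100.0


def uniform(values, rate=RATE):
    return UniformSeries(rate=rate, t0=0.0, values=np.asarray(values, dtype=float))


def deviation(values, rate=RATE):
    return DeviationSeries(rate=rate, x_cm=np.asarray(values, dtype=float))


def piecewise(vertices, seg_s=1.0, rate=RATE):
    """Piecewise-linear series through vertices, seg_s seconds per segment."""
    n_seg = int(seg_s * rate)
    parts = [np.linspace(a, b, n_seg + 1)[:-1] for a, b in zip(vertices, vertices[1:])]
    return np.concatenate(parts + [[vertices[-1]]])


class TestReconstructLateral:
    def test_centered_marker_is_zero(self):
        lat = reconstruct_lateral(uniform(np.zeros(201)), uniform(np.full(201, 150.0)))
        np.testing.assert_allclose(lat.values, 0.0)

    def test_pinhole_arithmetic(self):
        lat = reconstruct_lateral(
            uniform([100.0, 100.0]), uniform([150.0, 150.0]), focal_px=1000.0
        )
        np.testing.assert_allclose(lat.values, 15.0)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError, match="invalid range"):
            reconstruct_lateral(uniform([1.0, 1.0]), uniform([150.0, 0.0]))

    def test_noiseless_synthetic_reconstruction_rms(self):
        from vestigait.io import resample_uniform
        from vestigait.simulate import SynthConfig, simulate_trial, true_lateral

        cfg = SynthConfig(sway_amp_cm=8.0, seed=5).noiseless()
        trial, _ = simulate_trial(cfg)
        uni = resample_uniform({"camera": trial.camera, "ultrasonic": trial.ultrasonic}, 100.0)
        lat = reconstruct_lateral(uni["camera"], uni["ultrasonic"], cfg.focal_px)
        truth = true_lateral(cfg, lat.times)
        rms = np.sqrt(np.mean((lat.values - truth) ** 2))
        assert rms < 0.5


class TestVirtualLine:
    def test_constant_becomes_zero(self):
        dev = subtract_virtual_line(uniform(np.full(100, 7.0)))
        np.testing.assert_allclose(dev.x_cm, 0.0, atol=1e-12)

    def test_line_absorbs_linear_drift(self):
        t = np.arange(500) / RATE
        dev = subtract_virtual_line(uniform(3.0 * t))
        np.testing.assert_allclose(dev.x_cm, 0.0, atol=1e-9)

    def test_whole_cycle_sinusoid_unchanged(self):
        t = np.arange(0, 3.01, 0.01)  # exactly 3 cycles at 1 Hz
        v = 10.0 * np.sin(2 * np.pi * t)
        dev = subtract_virtual_line(uniform(v))
        np.testing.assert_allclose(dev.x_cm, v, atol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            subtract_virtual_line(uniform([1.0]))


class TestXCoB:
    def test_straight_walk_is_zero(self):
        assert compute_xcob(deviation(np.zeros(100)), 170.0) == 0.0

    def test_sinusoid_against_dense_numeric_oracle(self):
        t = np.arange(0, 5.01, 0.01)
        got = compute_xcob(deviation(10.0 * np.sin(2 * np.pi * t)), 170.0)
        # oracle: numeric mean of |10 sin| on a 10 kHz grid, normalized by 85 cm
        t_dense = np.arange(0, 5.0, 1e-4)
        want = 100.0 * np.mean(np.abs(10.0 * np.sin(2 * np.pi * t_dense))) / 85.0
        assert got == pytest.approx(want, abs=0.05)

    def test_constant_magnitude_alternation(self):
        x = np.tile([5.0, -5.0], 50)
        assert compute_xcob(deviation(x), 200.0) == pytest.approx(5.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        offset=st.floats(min_value=-50.0, max_value=50.0),
        slope=st.floats(min_value=-10.0, max_value=10.0),
    )
    def test_xcob_invariant_to_any_affine_drift(self, offset, slope):
        t = np.arange(0, 5.01, 0.01)
        sway = 10.0 * np.sin(2 * np.pi * t)
        base = compute_xcob(subtract_virtual_line(uniform(sway)), 170.0)
        moved = compute_xcob(subtract_virtual_line(uniform(sway + offset + slope * t)), 170.0)
        assert moved == pytest.approx(base, rel=1e-6, abs=1e-9)

    def test_drift_and_offset_invariance(self):
        t = np.arange(0, 5.01, 0.01)
        sway = 10.0 * np.sin(2 * np.pi * t)
        base = compute_xcob(subtract_virtual_line(uniform(sway)), 170.0)
        shifted = compute_xcob(subtract_virtual_line(uniform(sway + 4.0 + 2.5 * t)), 170.0)
        assert shifted == pytest.approx(base, rel=1e-6)

    def test_scales_with_amplitude_and_inverse_height(self):
        t = np.arange(0, 5.01, 0.01)
        x1 = compute_xcob(deviation(2.0 * np.sin(2 * np.pi * t)), 170.0)
        x2 = compute_xcob(deviation(4.0 * np.sin(2 * np.pi * t)), 170.0)
        x3 = compute_xcob(deviation(2.0 * np.sin(2 * np.pi * t)), 85.0)
        assert x2 == pytest.approx(2.0 * x1, rel=1e-9)
        assert x3 == pytest.approx(2.0 * x1, rel=1e-9)


class TestRPLP:
    def test_sinusoid_peaks(self):
        t = np.arange(0, 5.01, 0.01)
        rp, lp = compute_rp_lp(deviation(10.0 * np.sin(2 * np.pi * t)))
        step = 10.0 * 2 * np.pi / RATE  # one-sample amplitude slack
        assert rp == pytest.approx(10.0, abs=step)
        assert lp == pytest.approx(10.0, abs=step)

    def test_flat_series_has_no_extrema(self):
        assert compute_rp_lp(deviation(np.zeros(300))) == (0.0, 0.0)

    def test_hand_enumerated_piecewise_toy(self):
        x = piecewise([0.0, 4.0, -2.0, 8.0, -6.0, 0.0])
        rp, lp = compute_rp_lp(deviation(x))
        assert rp == pytest.approx(6.0)  # mean of peaks 4 and 8
        assert lp == pytest.approx(4.0)  # mean of |{-2, -6}|


class TestMLW:
    def test_stationary_sinusoid_width(self):
        t = np.arange(0, 5.01, 0.01)
        mlw = compute_mlw(deviation(10.0 * np.sin(2 * np.pi * t)))
        assert mlw == pytest.approx(20.0, abs=10.0 * 2 * np.pi / RATE)

    def test_flat_series_is_zero(self):
        assert compute_mlw(deviation(np.zeros(300))) == 0.0

    def test_amplitude_change_gives_largest_width(self):
        t = np.arange(0, 6.01, 0.01)
        x = np.where(t < 3.0, 5.0, 12.0) * np.sin(2 * np.pi * t)
        mlw = compute_mlw(deviation(x))
        assert mlw == pytest.approx(24.0, abs=12.0 * 2 * np.pi / RATE)

    def test_range_fallback_matches_envelope_for_stationary(self):
        t = np.arange(0, 5.01, 0.01)
        dev = deviation(10.0 * np.sin(2 * np.pi * t))
        assert compute_mlw(dev, mode="range") == pytest.approx(compute_mlw(dev), abs=0.1)

    def test_envelope_width_bounds_peak_plus_valley(self):
        # stationary oscillation: MLW >= largest peak + largest valley magnitude
        t = np.arange(0, 5.01, 0.01)
        dev = deviation(7.0 * np.sin(2 * np.pi * t))
        rp, lp = compute_rp_lp(dev)
        assert compute_mlw(dev) >= max(rp, lp)
        assert compute_mlw(dev) >= 7.0 + 7.0 - 7.0 * 2 * np.pi / RATE
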