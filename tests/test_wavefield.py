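"""Displacement extraction and the filter chain."""

import numpy as np
import pytest

from ocevel.synthetic import SimConfig, simulate_displacement
from ocevel.wavefield import (
    directional_filter,
    displacement_pipeline,
    lowpass_filter,
    median_filter_3d,
    normalize_particles,
    phase_difference,
    phase_to_displacement,
)


class TestPhaseDifference:
    def test_constant_column_gives_zeros(self):
        assert np.allclose(phase_difference(np.full((3, 8), 1.2)), 0.0)

    def test_plain_arithmetic(self):
        out = phase_difference(np.array([[0.0, np.pi / 2, np.pi]]))
        np.testing.assert_allclose(out, [[np.pi / 2, np.pi / 2]])

    def test_wrapping_across_boundary(self):
        # 3 -> -3 rad is a -6 rad step, wrapped to 2*pi - 6 ~ 0.2832
        out = phase_difference(np.array([[3.0, -3.0]]))
        assert out[0, 0] == pytest.approx(2 * np.pi - 6, abs=1e-12)

    def test_short_time_axis_rejected(self):
        with pytest.raises(ValueError, match="time extent"):
            phase_difference(np.ones((4, 1)))


class TestPhaseToDisplacement:
    def test_zero_maps_to_zero(self, geometry):
        assert phase_to_displacement(np.zeros((2, 2)), geometry).sum() == 0.0

    def test_known_value(self, geometry):
        # dphi=pi, lambda=1.310 um, n=1.38 -> 1.310/(4*1.38) um
        d = phase_to_displacement(np.array([[np.pi]]), geometry, refractive_index=1.38)
        assert d[0, 0] == pytest.approx(1.310 / (4 * 1.38), abs=1e-4)

    def test_inverse_identity(self, geometry):
        lam_um = geometry.wavelength_nm * 1e-3
        n = 1.38
        dphi = 4 * np.pi * n / lam_um  # phase of a 1 um displacement
        d = phase_to_displacement(np.array([[dphi]]), geometry, n)
        assert d[0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_bad_refractive_index(self, geometry):
        with pytest.raises(ValueError):
            phase_to_displacement(np.zeros((2, 2)), geometry, refractive_index=0.0)


def plane_wave(nx, nt, kx, kt):
    """Real plane wave cos(2pi(kx x/nx + kt t/nt)) on the DFT grid."""
    x = np.arange(nx)[:, None]
    t = np.arange(nt)[None, :]
    return np.cos(2 * np.pi * (kx * x / nx + kt * t / nt))


class TestDirectionalFilter:
    # kx=+8, kt=-10 pairing: phase kx*x - kt*t = constant along x increasing
    # with t -> forward (+x) propagation; energy off the guard band.

    def test_forward_wave_passes(self):
        w = plane_wave(64, 96, 8, -10)
        out = directional_filter(w, "forward")
        assert np.linalg.norm(out - w) / np.linalg.norm(w) < 1e-6

    def test_backward_wave_rejected(self):
        w = plane_wave(64, 96, 8, 10)
        out = directional_filter(w, "forward")
        assert np.sum(out**2) < 1e-6 * np.sum(w**2)

    def test_mixture_keeps_forward_component_only(self):
        fwd = plane_wave(64, 96, 8, -10)
        bwd = plane_wave(64, 96, 6, 12)
        out = directional_filter(fwd + bwd, "forward")
        assert np.linalg.norm(out - fwd) / np.linalg.norm(fwd) < 0.01

    def test_backward_direction_mirrors(self):
        bwd = plane_wave(64, 96, 8, 10)
        out = directional_filter(bwd, "backward")
        assert np.linalg.norm(out - bwd) / np.linalg.norm(bwd) < 1e-6

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=(48, 64))
        once = directional_filter(d)
        twice = directional_filter(once)
        assert np.linalg.norm(twice - once) / np.linalg.norm(once) < 1e-10

    def test_guard_band_preserves_long_wavelengths_both_ways(self):
        # |kx| <= guard: direction unresolvable at this aperture, kept
        w = plane_wave(64, 96, 2, 10)
        out = directional_filter(w, "forward", guard_bins=3)
        assert np.linalg.norm(out - w) / np.linalg.norm(w) < 1e-6


class TestLowpassFilter:
    def tone(self, geometry, f_hz, nt=2048):
        t = np.arange(nt) / geometry.aline_rate_hz
        return np.sin(2 * np.pi * f_hz * t)[None, :]

    def test_dc_unchanged(self, geometry):
        out = lowpass_filter(np.ones((3, 256)), 2000.0, geometry)
        np.testing.assert_allclose(out, 1.0, rtol=1e-9)

    def test_passband_gain(self, geometry):
        x = self.tone(geometry, 500.0)
        y = lowpass_filter(x, 2000.0, geometry)
        core = slice(256, -256)  # avoid filtfilt edge transients
        assert np.abs(y[0, core]).max() >= 0.99 * np.abs(x[0, core]).max()

    def test_stopband_attenuation(self, geometry):
        x = self.tone(geometry, 10_000.0)
        y = lowpass_filter(x, 2000.0, geometry)
        core = slice(256, -256)
        assert np.abs(y[0, core]).max() <= 0.1 * np.abs(x[0, core]).max()

    def test_cutoff_above_nyquist_rejected(self, geometry):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(np.ones((2, 64)), 50_000.0, geometry)


class TestMedianFilter:
    def test_constant_volume_unchanged(self):
        v = np.full((3, 15, 9), 2.5)
        np.testing.assert_array_equal(median_filter_3d(v), v)

    def test_impulse_removed(self):
        v = np.zeros((1, 21, 15))
        v[0, 10, 7] = 100.0
        assert np.all(median_filter_3d(v) == 0.0)

    def test_matches_naive_sliding_median(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(7, 21, 15))
        kernel = (1, 11, 5)
        out = median_filter_3d(v, kernel)
        pads = tuple((k // 2, k // 2) for k in kernel)
        vp = np.pad(v, pads, mode="symmetric")  # edge-inclusive reflection
        naive = np.empty_like(v)
        for i in range(v.shape[0]):
            for j in range(v.shape[1]):
                for k in range(v.shape[2]):
                    naive[i, j, k] = np.median(
                        vp[i : i + kernel[0], j : j + kernel[1], k : k + kernel[2]]
                    )
        np.testing.assert_array_equal(out, naive)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            median_filter_3d(np.zeros((3, 5, 5)), (1, 4, 3))


class TestNormalizeParticles:
    def test_live_columns_peak_at_one(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=(12, 30)) + 2.0
        s = normalize_particles(d)
        np.testing.assert_allclose(s.values.max(axis=1), 1.0, rtol=1e-12)
        assert not s.dead_columns.any()

    def test_dead_column_zeroed_and_flagged(self):
        d = np.zeros((3, 10))
        d[1] = 1.0
        s = normalize_particles(d)
        assert s.dead_columns.tolist() == [True, False, True]
        assert np.all(s.values[0] == 0.0)

    def test_scaling_by_column_max(self):
        d = np.zeros((1, 4))
        d[0] = [0.5, 2.0, 1.0, -1.0]
        s = normalize_particles(d)
        np.testing.assert_allclose(s.values[0], [0.25, 1.0, 0.5, -0.5])


class TestPipeline:
    def test_filter_tags_record_fixed_order(self, noiseless_volume, geometry):
        _, vol = noiseless_volume
        slices, tags = displacement_pipeline(vol.phase, geometry)
        assert tags[0] == "phase_difference"
        assert tags[1] == "phase_to_displacement"
        assert tags[2].startswith("directional")
        assert tags[3].startswith("lowpass")
        assert tags[4].startswith("median")
        assert tags[-1] == "normalize_particles"
        assert len(slices) == vol.phase.shape[0]

    def test_ridge_tracks_oracle_within_two_samples_under_noise(self, geometry):
        cfg = SimConfig(
            velocity_mps=4.0, depth_px=1, lateral_px=160, time_px=256,
            noise_sigma_rad=0.3, n_pulses=1, seed=23,
        )
        clean = simulate_displacement(cfg, geometry)[0]
        from ocevel.synthetic import displacement_to_phase

        vol = displacement_to_phase(clean[None] if clean.ndim == 2 else clean, geometry, cfg)
        slices, _ = displacement_pipeline(vol.phase, geometry)
        final = slices[0].values
        # compare ridges away from window edges; the phase-difference step
        # shifts the ridge by a constant lag, so compare after removing the
        # median offset
        lo, hi = 10, 150
        oracle = np.argmax(clean, axis=1)[lo:hi]
        got = np.argmax(final, axis=1)[lo:hi]
        resid = got - oracle
        offset = (resid.min() + resid.max()) / 2  # the constant lag itself
        assert np.abs(resid - offset).max() <= 2
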