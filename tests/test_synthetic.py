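"""Synthetic acquisition generator: ridge geometry, wrapping, determinism."""

import numpy as np
import pytest

from ocevel.core import wrap_phase
from ocevel.synthetic import (
    SimConfig,
    displacement_to_phase,
    make_dataset,
    simulate_displacement,
    simulate_volume,
)


def ridge_slope(field2d, lo, hi):
    """Least-squares slope (samples/px) of the argmax ridge on [lo, hi)."""
    x = np.arange(lo, hi)
    t = np.argmax(field2d[lo:hi], axis=1)
    return np.polyfit(x, t, 1)[0]


class TestSimulateDisplacement:
    def test_unit_slope_velocity_matches_geometry(self, geometry):
        # 21.7 um x 92 kHz = 1.9964 m/s <-> exactly 1 px per time sample
        v = geometry.velocity_from_slope(1.0)
        assert v == pytest.approx(1.9964, abs=1e-4)
        cfg = SimConfig(
            velocity_mps=v, depth_px=1, lateral_px=64, time_px=160,
            lateral_attenuation_per_mm=0, depth_attenuation_per_mm=0,
            n_pulses=1, seed=0,
        )
        d = simulate_displacement(cfg, geometry)[0]
        t = np.argmax(d, axis=1)
        assert np.all(np.diff(t) == 1)

    def test_no_attenuation_gives_uniform_peak_amplitude(self, geometry):
        # integer-slope velocity so every column samples the packet peak
        v = geometry.velocity_from_slope(1.0)
        cfg = SimConfig(
            velocity_mps=v, depth_px=3, lateral_px=48, time_px=128,
            lateral_attenuation_per_mm=0, depth_attenuation_per_mm=0,
            n_pulses=1, seed=0,
        )
        d = simulate_displacement(cfg, geometry)
        peaks = np.abs(d).max(axis=2)
        assert np.allclose(peaks, peaks[0, 0], rtol=1e-5)

    def test_piecewise_velocity_recovers_segment_slopes(self, geometry):
        cfg = SimConfig(
            velocity_mps=[(0, 128, 4.0), (128, 256, 9.0)],
            depth_px=1, lateral_px=256, time_px=320,
            lateral_attenuation_per_mm=0, depth_attenuation_per_mm=0,
            noise_sigma_rad=0.0, n_pulses=1, seed=0,
        )
        d = simulate_displacement(cfg, geometry)[0]
        for lo, hi, v_true in [(10, 120, 4.0), (140, 250, 9.0)]:
            s = ridge_slope(d, lo, hi)
            v_est = geometry.velocity_from_slope(s)
            assert v_est == pytest.approx(v_true, rel=0.02)

    @pytest.mark.parametrize("v", [2.0, 4.0, 8.0, 16.0])
    def test_homogeneous_ridge_slope_identity(self, geometry, v):
        cfg = SimConfig(
            velocity_mps=v, depth_px=1, lateral_px=256, time_px=512,
            lateral_attenuation_per_mm=0, depth_attenuation_per_mm=0,
            n_pulses=1, seed=0,
        )
        d = simulate_displacement(cfg, geometry)[0]
        v_est = geometry.velocity_from_slope(ridge_slope(d, 5, 250))
        assert v_est == pytest.approx(v, rel=0.01)

    def test_nonpositive_velocity_rejected_with_segment_name(self):
        cfg = SimConfig(velocity_mps=[(0, 32, 5.0), (32, 64, -1.0)], lateral_px=64)
        with pytest.raises(ValueError, match="segment 1"):
            cfg.segments()

    def test_segments_must_tile_lateral_range(self):
        with pytest.raises(ValueError, match="tile"):
            SimConfig(velocity_mps=[(0, 30, 5.0), (40, 64, 6.0)], lateral_px=64).segments()


class TestDisplacementToPhase:
    def test_zero_amplitude_gives_time_constant_phase(self, geometry):
        cfg = SimConfig(
            velocity_mps=5.0, depth_px=2, lateral_px=16, time_px=32,
            amplitude_rad=0.0, noise_sigma_rad=0.0, seed=3,
        )
        d = simulate_displacement(cfg, geometry)
        vol = displacement_to_phase(d, geometry, cfg)
        assert np.allclose(vol.phase, vol.phase[:, :, :1])

    def test_output_wrapped(self, noisy_volume):
        _, vol = noisy_volume
        assert vol.phase.min() >= -np.pi - 1e-6
        assert vol.phase.max() <= np.pi + 1e-6

    def test_seed_determinism(self, geometry):
        cfg = SimConfig(velocity_mps=7.0, depth_px=2, lateral_px=24, time_px=48, seed=5)
        a = simulate_volume(cfg, geometry).phase
        b = simulate_volume(cfg, geometry).phase
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("artifact", ["drift", "jump"])
    def test_motion_artifacts_stay_wrapped(self, geometry, artifact):
        cfg = SimConfig(
            velocity_mps=5.0, depth_px=2, lateral_px=16, time_px=64,
            motion_artifact=artifact, seed=9,
        )
        vol = simulate_volume(cfg, geometry)
        assert np.abs(vol.phase).max() <= np.pi + 1e-6

    def test_wrap_conservation_modulo_two_pi(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-20, 20, size=1000)
        k = (wrap_phase(x) - x) / (2 * np.pi)
        assert np.allclose(k, np.round(k), atol=1e-9)


@pytest.fixture(scope="module")
def configs():
    rng = np.random.default_rng(21)
    return [
        SimConfig(
            velocity_mps=float(rng.uniform(2, 16)), depth_px=4,
            lateral_px=56, time_px=56, seed=int(rng.integers(2**31)),
        )
        for _ in range(10)
    ]


class TestMakeDataset:

    def test_volume_ids_never_shared_between_splits(self, configs, geometry):
        ds = make_dataset(configs, geometry, split=(0.7, 0.15, 0.15), slice_size=48, seed=1)
        assert ds.ids("train") & ds.ids("val") == set()
        assert ds.ids("train") & ds.ids("test") == set()
        assert ds.ids("val") & ds.ids("test") == set()
        n = sum(len(part[1]) for part in (ds.train, ds.val, ds.test))
        assert n == 10 * 4

    def test_oracle_labels_match_configured_velocity(self, geometry):
        configs = [
            SimConfig(velocity_mps=5.0, depth_px=3, lateral_px=56, time_px=56, seed=s)
            for s in range(4)
        ]
        ds = make_dataset(configs, geometry, slice_size=48, seed=2)
        for part in (ds.train, ds.val, ds.test):
            assert np.allclose(part[1], 5.0)

    def test_slices_normalised_to_unit_interval(self, configs, geometry):
        ds = make_dataset(configs, geometry, slice_size=48, seed=3)
        x = ds.train[0]
        assert x.shape[1:] == (48, 48, 1)
        assert x.min() >= 0.0 and x.max() <= 1.0

    def test_empty_config_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            make_dataset([])

    def test_bad_split_rejected(self, configs):
        with pytest.raises(ValueError, match="sum to 1"):
            make_dataset(configs, split=(0.5, 0.2, 0.2))

    def test_tof_labels_agree_with_oracle_on_noiseless_volume(self, geometry):
        configs = [
            SimConfig(
                velocity_mps=5.0, depth_px=3, lateral_px=200, time_px=256,
                noise_sigma_rad=0.0, lateral_attenuation_per_mm=0.0,
                depth_attenuation_per_mm=0.0, n_pulses=1, seed=7,
            )
        ]
        ds = make_dataset(
            configs, geometry, split=(1.0, 0.0, 0.0), label_source="tof",
            slice_size=192, seed=4, crop_random=False,
        )
        labels = ds.train[1]
        assert len(labels) > 0
        assert np.allclose(labels, 5.0, rtol=0.02)
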