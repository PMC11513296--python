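"""Shared fixtures: small simulated volumes and geometries."""

from __future__ import annotations

import pytest

from ocevel.core import ScanGeometry
from ocevel.synthetic import SimConfig, simulate_volume


@pytest.fixture(scope="session")
def geometry() -> ScanGeometry:
    return ScanGeometry()


@pytest.fixture(scope="session")
def noiseless_volume(geometry):
    """Small noiseless single-pulse acquisition at 5 m/s."""
    cfg = SimConfig(
        velocity_mps=5.0,
        depth_px=6,
        lateral_px=96,
        time_px=160,
        noise_sigma_rad=0.0,
        lateral_attenuation_per_mm=0.0,
        depth_attenuation_per_mm=0.0,
        n_pulses=1,
        seed=11,
    )
    return cfg, simulate_volume(cfg, geometry)


@pytest.fixture(scope="session")
def noisy_volume(geometry):
    """Moderate-noise single-pulse acquisition at 5 m/s."""
    cfg = SimConfig(
        velocity_mps=5.0,
        depth_px=4,
        lateral_px=96,
        time_px=160,
        noise_sigma_rad=0.3,
        n_pulses=1,
        seed=13,
    )
    return cfg, simulate_volume(cfg, geometry)
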