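"""Cropping and phase normalisation: raw volumes -> network-ready slices.

The raw acquisition window includes the head of the piezoelectric
actuator; a fixed lateral/time crop removes it and retains the region of
interest.  Wrapped phase in [-pi, pi] is then mapped affinely onto
[0, 1], which is the input scale of the regression network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import RawPhaseVolume

__all__ = [
    "CROP_SIZE",
    "NormalizedSlice",
    "crop_volume",
    "normalize_phase",
    "denormalize_phase",
]

#: Canonical lateral x time crop of a full 512^3 acquisition.
CROP_SIZE = (320, 320)

#: Default lateral offset of the crop window (actuator head removed).
DEFAULT_LATERAL_OFFSET = 96


@dataclass
class NormalizedSlice:
    """A single lateral x time phase slice scaled to [0, 1]."""

    values: np.ndarray
    depth_index: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError("NormalizedSlice values must be 2-D (lateral x time)")
        if float(v.min()) < 0.0 or float(v.max()) > 1.0:
            raise ValueError("NormalizedSlice values must lie in [0, 1]")


def crop_volume(
    vol: RawPhaseVolume,
    lateral_offset: int = DEFAULT_LATERAL_OFFSET,
    time_offset: int = 0,
    size: tuple[int, int] = CROP_SIZE,
) -> RawPhaseVolume:
    """Crop the lateral/time axes to contiguous windows; depth untouched.

    ``size`` defaults to the canonical 320 x 320 window; a smaller size
    supports desk-scale experiments with proportionally smaller volumes.
    """
    nz, nx, nt = vol.phase.shape
    lat_len, t_len = size
    if lateral_offset < 0 or time_offset < 0:
        raise ValueError("crop offsets must be non-negative")
    if lateral_offset + lat_len > nx:
        raise ValueError(
            f"lateral crop window [{lateral_offset}, {lateral_offset + lat_len}) "
            f"exceeds lateral extent {nx}"
        )
    if time_offset + t_len > nt:
        raise ValueError(
            f"time crop window [{time_offset}, {time_offset + t_len}) "
            f"exceeds time extent {nt}"
        )
    phase = vol.phase[:, lateral_offset : lateral_offset + lat_len, time_offset : time_offset + t_len]
    return RawPhaseVolume(
        phase=phase,
        geometry=vol.geometry,
        oracle_velocity=vol.oracle_velocity,
        oracle_segments=[
            (max(a - lateral_offset, 0), min(b - lateral_offset, lat_len))
            for a, b in vol.oracle_segments
            if b > lateral_offset and a < lateral_offset + lat_len
        ],
        source_id=vol.source_id,
    )


def normalize_phase(phase: np.ndarray) -> np.ndarray:
    """Map wrapped phase [-pi, pi] affinely onto [0, 1].

    out = phase / pi * 0.5 + 0.5, so -pi -> 0, 0 -> 0.5, pi -> 1.
    Values outside [-pi, pi] are rejected rather than silently wrapped,
    to surface upstream wrapping bugs.
    """
    p = np.asarray(phase)
    # float32 round-off of pi itself is tolerated; anything larger is a bug
    if float(np.abs(p).max(initial=0.0)) > np.pi * (1 + 1e-6):
        raise ValueError("phase outside [-pi, pi]; wrap before normalising")
    return np.clip(p / np.pi * 0.5 + 0.5, 0.0, 1.0)


def denormalize_phase(values: np.ndarray) -> np.ndarray:
    """Exact affine inverse of :func:`normalize_phase`."""
    return (np.asarray(values) - 0.5) * 2.0 * np.pi
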