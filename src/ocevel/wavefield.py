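"""Raw phase -> filtered, normalised axial-displacement wave fields.

The phase difference between consecutive A-lines measures sub-resolution
axial displacement.  Before time-of-flight fitting, the displacement
field is cleaned in a fixed order: an f-k directional filter suppresses
reflected (backward-travelling) waves, a zero-phase 2 kHz low-pass
removes high-frequency noise without shifting arrival times, a median
filter removes impulsive speckle outliers, and each lateral position
("particle") is normalised by its own temporal maximum so the main-peak
amplitude is comparable across the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .core import ScanGeometry, wrap_phase

__all__ = [
    "DisplacementSlice",
    "phase_difference",
    "phase_to_displacement",
    "directional_filter",
    "lowpass_filter",
    "median_filter_3d",
    "normalize_particles",
    "displacement_pipeline",
]

#: Columns whose temporal maximum falls at or below this are "dead".
DEAD_COLUMN_EPS = 1e-12

#: Refractive index of soft tissue, used for the displacement scale.
DEFAULT_REFRACTIVE_INDEX = 1.38


@dataclass
class DisplacementSlice:
    """Normalised displacement field (lateral x time) at one depth."""

    values: np.ndarray
    depth_index: int = 0
    filters_applied: list[str] = field(default_factory=list)
    dead_columns: np.ndarray | None = None  # bool per lateral position


def phase_difference(phase: np.ndarray) -> np.ndarray:
    """Wrapped phase difference between consecutive time samples.

    out[..., t] = wrap(in[..., t+1] - in[..., t]); the time axis is the
    last axis and shrinks by one.
    """
    p = np.asarray(phase, dtype=np.float64)
    if p.shape[-1] < 2:
        raise ValueError("phase_difference needs a time extent of at least 2")
    return wrap_phase(np.diff(p, axis=-1))


def phase_to_displacement(
    dphi: np.ndarray,
    geometry: ScanGeometry | None = None,
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX,
) -> np.ndarray:
    """Axial displacement (micrometres) from a wrapped phase difference.

    d = dphi * lambda0 / (4 * pi * n).  The absolute scale cancels in the
    later particle normalisation, but is applied consistently so that
    intermediate fields carry physical units.
    """
    if refractive_index <= 0:
        raise ValueError("refractive_index must be positive")
    geometry = geometry or ScanGeometry()
    lam_um = geometry.wavelength_nm * 1e-3
    return np.asarray(dphi) * lam_um / (4.0 * np.pi * refractive_index)


#: Spatial-frequency guard band (DFT bins) of the directional filter.
DIRECTIONAL_GUARD_BINS = 3


def directional_filter(
    disp: np.ndarray, direction: str = "forward", guard_bins: int = DIRECTIONAL_GUARD_BINS
) -> np.ndarray:
    """Keep one lateral propagation direction via f-k quadrant masking.

    The 2-D Fourier transform over (lateral, time) separates waves by the
    sign pairing of lateral wavenumber and temporal frequency: a wave
    moving toward +x occupies the quadrants where the two signs are
    opposite.  Coefficients of the rejected direction are zeroed and the
    real part of the inverse transform returned.  The DC row/column is
    kept, together with a ``guard_bins``-wide band of spatial
    frequencies around it: at wavelengths comparable to (or longer than)
    the lateral aperture the propagation direction is not resolvable,
    and hard-masking that near-DC leakage would skew the wavefront of a
    legitimate forward wave.  Waves within the guard band therefore pass
    in both directions.  The mask is a projection, so the filter is
    idempotent.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    d = np.asarray(disp, dtype=np.float64)
    if d.ndim != 2:
        raise ValueError("directional_filter expects a 2-D (lateral x time) field")
    spec = np.fft.fft2(d)
    kx = np.rint(np.fft.fftfreq(d.shape[0]) * d.shape[0]).astype(int)[:, None]
    kt = np.rint(np.fft.fftfreq(d.shape[1]) * d.shape[1]).astype(int)[None, :]
    sx, st = np.sign(kx), np.sign(kt)
    # Nyquist bins pair with themselves under conjugation; masking them on
    # one side only would break Hermitian symmetry (and idempotence), so
    # they are treated like DC and kept.
    if d.shape[0] % 2 == 0:
        sx[kx == -(d.shape[0] // 2)] = 0
    if d.shape[1] % 2 == 0:
        st[kt == -(d.shape[1] // 2)] = 0
    sign_product = sx * st
    wanted = -1 if direction == "forward" else 1
    reject = (sign_product == -wanted) & (np.abs(kx) > guard_bins)
    spec = np.where(reject, 0.0, spec)
    return np.fft.ifft2(spec).real


def lowpass_filter(
    disp: np.ndarray,
    cutoff_hz: float = 2000.0,
    geometry: ScanGeometry | None = None,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the time (last) axis.

    Applied forward-backward (filtfilt) so arrival times — which the
    time-of-flight fit depends on — are not shifted.
    """
    geometry = geometry or ScanGeometry()
    nyquist = geometry.aline_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at or above Nyquist ({nyquist} Hz)")
    sos = signal.butter(order, cutoff_hz, fs=geometry.aline_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(disp, dtype=np.float64), axis=-1)


def median_filter_3d(
    disp_volume: np.ndarray, kernel: tuple[int, int, int] = (1, 11, 5)
) -> np.ndarray:
    """Sliding-window median over (depth, lateral, time), reflected edges.

    Default kernel (1, 11, 5) filters 11 x 5 (lateral x time) windows
    within each depth layer, preserving depth-local velocity structure.
    """
    if any(k % 2 == 0 for k in kernel):
        raise ValueError(f"median kernel must be odd in every axis, got {kernel}")
    d = np.asarray(disp_volume)
    if d.ndim != 3:
        raise ValueError("median_filter_3d expects a (depth, lateral, time) volume")
    return ndimage.median_filter(d, size=kernel, mode="reflect")


def normalize_particles(disp: np.ndarray, depth_index: int = 0) -> DisplacementSlice:
    """Divide each lateral column by its own maximum over time.

    Columns whose maximum is at or below ``DEAD_COLUMN_EPS`` carry no
    wave signal; they are zeroed and flagged dead so downstream tracking
    can exclude them.
    """
    d = np.asarray(disp, dtype=np.float64)
    if not np.all(np.isfinite(d)):
        raise ValueError("normalize_particles requires finite values")
    col_max = d.max(axis=-1)
    dead = col_max <= DEAD_COLUMN_EPS
    scale = np.where(dead, 1.0, col_max)
    out = d / scale[:, None]
    out[dead] = 0.0
    return DisplacementSlice(
        values=out,
        depth_index=depth_index,
        filters_applied=["normalize_particles"],
        dead_columns=dead,
    )


def displacement_pipeline(
    phase_volume: np.ndarray,
    geometry: ScanGeometry | None = None,
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX,
    use_directional: bool = True,
    cutoff_hz: float = 2000.0,
    median_kernel: tuple[int, int, int] = (1, 11, 5),
) -> tuple[list[DisplacementSlice], list[str]]:
    """Full wave-extraction chain on a (depth x lateral x time) volume.

    Fixed order: phase difference -> displacement -> directional filter
    -> low-pass -> 3-D median -> per-particle normalisation.  Returns one
    :class:`DisplacementSlice` per depth layer plus the applied-filter
    tags shared by all of them.
    """
    geometry = geometry or ScanGeometry()
    dphi = phase_difference(phase_volume)
    disp = phase_to_displacement(dphi, geometry, refractive_index)
    tags = ["phase_difference", "phase_to_displacement"]

    if use_directional:
        disp = np.stack([directional_filter(layer, "forward") for layer in disp])
        tags.append("directional:forward")
    disp = lowpass_filter(disp, cutoff_hz, geometry)
    tags.append(f"lowpass:{cutoff_hz:g}Hz")
    disp = median_filter_3d(disp, median_kernel)
    tags.append(f"median:{median_kernel}")

    # Zero-phase filtering leaves transients at the window ends that can
    # exceed the wave peak under noise; exclude them from peak tracking.
    guard = min(disp.shape[-1] // 6, max(int(geometry.aline_rate_hz / cutoff_hz) // 2, 1))
    if guard > 0:
        disp[..., :guard] = 0.0
        disp[..., -guard:] = 0.0
        tags.append(f"edge_trim:{guard}")

    slices = []
    for z in range(disp.shape[0]):
        s = normalize_particles(disp[z], depth_index=z)
        s.filters_applied = tags + ["normalize_particles"]
        slices.append(s)
    return slices, tags + ["normalize_particles"]
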