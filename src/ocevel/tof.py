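"""Time-of-flight SAW velocity estimation by main-peak tracking.

For each depth layer the main wavefront peak — the temporal maximum of
the normalised displacement at each lateral position — traces a
space-time curve whose slope is the inverse wave velocity (V = dx/dt).
A linear least-squares fit of peak time against lateral distance, with
iterative MAD-based outlier rejection, yields the per-layer ground-truth
velocity used to label training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ScanGeometry
from .wavefield import DisplacementSlice

__all__ = [
    "WavefrontTrack",
    "VelocityEstimate",
    "DepthVelocityProfile",
    "track_wavefront",
    "fit_velocity",
    "profile_volume",
]

#: Depth-layer cap of the conventional estimator.
MAX_DEPTH_LAYERS = 300

#: Per-layer robust-refit loop: stop when the relative slope change
#: drops below this, or after this many refit iterations.
FIT_RTOL = 1e-6
FIT_MAX_ITER = 300


@dataclass
class WavefrontTrack:
    """Main-peak arrival time (sample index) per lateral position."""

    peak_time_sample: np.ndarray  # int, per lateral position in window
    valid_mask: np.ndarray  # bool, same length
    lateral_index: np.ndarray  # absolute lateral pixel of each entry


@dataclass
class VelocityEstimate:
    """Fitted SAW velocity for one depth layer, with fit diagnostics."""

    velocity_mps: float
    intercept_sample: float
    r_squared: float
    n_points: int
    converged: bool
    depth_index: int = 0
    stop_reason: str = ""


@dataclass
class DepthVelocityProfile:
    """Ordered per-depth-layer estimates plus a converged-layer summary."""

    estimates: list[VelocityEstimate] = field(default_factory=list)

    def converged(self) -> list[VelocityEstimate]:
        return [e for e in self.estimates if e.converged]

    @property
    def summary(self) -> tuple[float, float]:
        """(mean, std) of velocity over converged layers; NaNs if none."""
        v = np.array([e.velocity_mps for e in self.converged()])
        if v.size == 0:
            return float("nan"), float("nan")
        return float(v.mean()), float(v.std())


def track_wavefront(
    disp: DisplacementSlice | np.ndarray,
    lateral_window: tuple[int, int] | None = None,
    pulse_period_samples: int | None = None,
) -> WavefrontTrack:
    """Locate the main wavefront peak at each lateral position.

    The peak is the argmax over time of the normalised displacement;
    ties break toward the earliest sample (first arrival).  When the
    excitation repeats (``pulse_period_samples``), the search is
    restricted to one inter-pulse interval after the earliest detected
    arrival, so the track cannot alias between successive packets.
    Dead columns (no signal) are masked out.
    """
    if isinstance(disp, DisplacementSlice):
        values = disp.values
        dead = disp.dead_columns
    else:
        values = np.asarray(disp)
        dead = None
    if values.ndim != 2:
        raise ValueError("track_wavefront expects a 2-D (lateral x time) slice")
    nx, nt = values.shape
    a, b = lateral_window if lateral_window is not None else (0, nx)
    if not (0 <= a < b <= nx):
        raise ValueError(f"lateral window [{a}, {b}) is empty or outside [0, {nx})")

    win = values[a:b]
    valid = np.ones(b - a, dtype=bool) if dead is None else ~dead[a:b]
    # np.argmax returns the first (earliest) index on ties
    peaks = np.argmax(win, axis=-1)

    if pulse_period_samples is not None and valid.any():
        t0 = int(peaks[valid].min())
        hi = min(t0 + int(pulse_period_samples), nt)
        peaks = t0 + np.argmax(win[:, t0:hi], axis=-1)

    return WavefrontTrack(
        peak_time_sample=peaks.astype(int),
        valid_mask=valid,
        lateral_index=np.arange(a, b),
    )


def _lstsq_line(x: np.ndarray, t: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line t = s*x + c; returns (s, c, r_squared)."""
    s, c = np.polyfit(x, t, 1)
    resid = t - (s * x + c)
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(s), float(c), r2


def fit_velocity(
    track: WavefrontTrack,
    geometry: ScanGeometry | None = None,
    depth_index: int = 0,
    rtol: float = FIT_RTOL,
    max_iter: int = FIT_MAX_ITER,
) -> VelocityEstimate:
    """Robust least-squares slope of peak time vs lateral distance.

    The fit regresses time shifts on propagation distances in index
    space; the slope s (samples per pixel) converts once to velocity via
    v = lateral_px_pitch * a_line_rate / s.  After each fit, points with
    residuals beyond 3x the median absolute deviation are discarded and
    the line refit, until the relative slope change falls below ``rtol``
    or ``max_iter`` refits have run.  A non-positive final slope (flat or
    backward ridge) yields a non-converged estimate.
    """
    geometry = geometry or ScanGeometry()
    x = track.lateral_index[track.valid_mask].astype(float)
    t = track.peak_time_sample[track.valid_mask].astype(float)
    if x.size < 3:
        raise ValueError(f"fit_velocity needs >= 3 valid points, got {x.size}")

    s, c, r2 = _lstsq_line(x, t)
    stop = "max_iter"
    for _ in range(max_iter):
        resid = np.abs(t - (s * x + c))
        mad = float(np.median(resid))
        keep = resid <= 3.0 * mad if mad > 0 else np.ones_like(resid, dtype=bool)
        if keep.sum() < 3:
            stop = "too_few_points"
            break
        s_new, c_new, r2 = _lstsq_line(x[keep], t[keep])
        rel = abs(s_new - s) / abs(s) if s != 0 else np.inf
        s, c = s_new, c_new
        x, t = x[keep], t[keep]
        if rel < rtol:
            stop = "slope_converged"
            break

    if s <= 1e-9:  # flat or backward ridge; 1e-9 samples/px is numerically zero
        return VelocityEstimate(
            velocity_mps=float("nan"),
            intercept_sample=c,
            r_squared=r2,
            n_points=int(x.size),
            converged=False,
            depth_index=depth_index,
            stop_reason=f"non-positive slope ({s:.3g} samples/px)",
        )
    velocity = geometry.velocity_from_slope(s)
    return VelocityEstimate(
        velocity_mps=float(velocity),
        intercept_sample=c,
        r_squared=r2,
        n_points=int(x.size),
        converged=stop in ("slope_converged", "max_iter"),
        depth_index=depth_index,
        stop_reason=stop,
    )


def profile_volume(
    disp_slices: list[DisplacementSlice],
    geometry: ScanGeometry | None = None,
    lateral_window: tuple[int, int] | None = None,
    max_layers: int = MAX_DEPTH_LAYERS,
    pulse_period_samples: int | None = None,
) -> DepthVelocityProfile:
    """Track + fit every depth layer from the surface down.

    Processing stops after ``max_layers`` layers (the conventional
    estimator caps at 300).  A ``lateral_window`` restricts the fit to a
    lesion region when one is present.  Layers where tracking or fitting
    fails are recorded as non-converged and excluded from the summary.
    """
    geometry = geometry or ScanGeometry()
    profile = DepthVelocityProfile()
    for disp in disp_slices[:max_layers]:
        try:
            track = track_wavefront(disp, lateral_window, pulse_period_samples)
            est = fit_velocity(track, geometry, depth_index=disp.depth_index)
        except ValueError as exc:
            est = VelocityEstimate(
                velocity_mps=float("nan"),
                intercept_sample=float("nan"),
                r_squared=float("nan"),
                n_points=0,
                converged=False,
                depth_index=disp.depth_index,
                stop_reason=str(exc),
            )
        profile.estimates.append(est)
    return profile
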