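"""Scan geometry, phase wrapping, and small shared helpers.

The M-B acquisition protocol samples one depth profile (A-line) per
lateral position and time instant, so a raw volume is indexed
(depth, lateral, time).  All physical conversions between pixel/sample
indices and metres/seconds go through :class:`ScanGeometry` so that unit
handling lives in exactly one place.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ScanGeometry",
    "wrap_phase",
    "config_hash",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Physical sampling geometry of a phase-sensitive OCT acquisition.

    Parameters
    ----------
    axial_um_per_px : float
        Axial (depth) sampling distance, micrometres per pixel.
    lateral_um_per_px : float
        Lateral sampling distance, micrometres per pixel.
    aline_rate_hz : float
        A-line (temporal) sampling rate in hertz.
    wavelength_nm : float
        Centre wavelength of the source in nanometres.
    """

    axial_um_per_px: float = 4.7
    lateral_um_per_px: float = 21.7
    aline_rate_hz: float = 92_000.0
    wavelength_nm: float = 1310.0

    def __post_init__(self) -> None:
        for name in ("axial_um_per_px", "lateral_um_per_px", "aline_rate_hz", "wavelength_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ScanGeometry.{name} must be strictly positive")

    @property
    def dt_s(self) -> float:
        """Temporal sampling interval in seconds."""
        return 1.0 / self.aline_rate_hz

    @property
    def dx_m(self) -> float:
        """Lateral sampling interval in metres."""
        return self.lateral_um_per_px * 1e-6

    def velocity_from_slope(self, samples_per_px: float) -> float:
        """Convert a wavefront slope (time samples per lateral pixel) to m/s.

        A slope of one sample per pixel corresponds to
        ``lateral_um_per_px * 1e-6 * aline_rate_hz`` m/s
        (1.9964 m/s at the default geometry).
        """
        return self.dx_m * self.aline_rate_hz / samples_per_px

    def slope_from_velocity(self, velocity_mps: float) -> float:
        """Inverse of :meth:`velocity_from_slope` (samples per lateral pixel)."""
        return self.dx_m * self.aline_rate_hz / velocity_mps

    def to_attrs(self) -> dict:
        return asdict(self)


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase into [-pi, pi).

    ``unwrap(wrap(x)) - x`` is a multiple of 2*pi elementwise; the
    half-open convention maps +pi to -pi, which downstream normalisation
    treats identically (both ends of the interval are valid inputs).
    """
    return (np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""

    def _default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=_default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
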