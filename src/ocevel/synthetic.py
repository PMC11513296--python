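"""Synthetic raw-phase OCE volumes with known surface-wave velocity.

Real wave-based OCE acquisitions of skin and agar phantoms are not
publicly deposited, so this module emulates them: a piezoelectric
actuator driven by a 2 kHz square wave launches surface acoustic wave
(SAW) packets that travel laterally at a configurable speed (optionally
piecewise, to mimic a stiff lesion embedded in softer tissue).  The
packets modulate the otherwise static speckle phase of each A-line
column; additive Gaussian phase noise, depth/lateral attenuation and
bulk-motion artifacts reproduce the appearance of in vivo raw phase
slices.  Because the generating velocity is known exactly ("oracle"),
every downstream stage — filtering, time-of-flight fitting, and the
learned regressor — can be validated quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ScanGeometry

__all__ = [
    "SimConfig",
    "RawPhaseVolume",
    "simulate_displacement",
    "displacement_to_phase",
    "simulate_volume",
    "DatasetSplits",
    "make_dataset",
]

# Velocity can be a scalar (homogeneous medium) or a list of
# (lateral_start_px, lateral_end_px, velocity_mps) segments.
VelocitySpec = float | Sequence[tuple[int, int, float]]


@dataclass
class SimConfig:
    """Parameters of one simulated OCE acquisition.

    Defaults mirror the acquisition conditions the package targets:
    2 kHz square-wave excitation at 60% duty cycle, 512^3 volumes, a
    1.5 rad peak phase modulation and moderate phase noise.
    """

    velocity_mps: VelocitySpec = 5.0
    excitation_hz: float = 2000.0
    duty_cycle: float = 0.6
    amplitude_rad: float = 1.5
    noise_sigma_rad: float = 0.2
    lateral_attenuation_per_mm: float = 0.1
    depth_attenuation_per_mm: float = 0.5
    motion_artifact: str = "none"  # none | drift | jump
    depth_px: int = 512
    lateral_px: int = 512
    time_px: int = 512
    seed: int = 0
    # Wave-packet shape: Gaussian-windowed cosine (Morlet-like), peaked
    # exactly at the arrival time so argmax tracking is unbiased.  The
    # envelope width keeps the packet (and its temporal derivative, which
    # is what consecutive-A-line phase differences measure) inside the
    # 2 kHz low-pass band.  The first rising edge is delayed so the full
    # packet of the nearest lateral position lies inside the window.
    pulse_center_hz: float = 1000.0
    pulse_sigma_s: float = 2.5e-4
    pulse_delay_s: float | None = None  # None -> 3 * pulse_sigma_s
    n_pulses: int | None = None  # None = full train over the time window

    def __post_init__(self) -> None:
        if not self.amplitude_rad >= 0:
            raise ValueError("amplitude_rad must be >= 0")
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty_cycle must lie in (0, 1)")
        if self.motion_artifact not in ("none", "drift", "jump"):
            raise ValueError(f"unknown motion_artifact {self.motion_artifact!r}")

    def segments(self) -> list[tuple[int, int, float]]:
        """Velocity specification as validated lateral segments."""
        v = self.velocity_mps
        if np.isscalar(v):
            segs = [(0, self.lateral_px, float(v))]
        else:
            segs = sorted((int(a), int(b), float(vv)) for a, b, vv in v)
        cursor = 0
        for idx, (a, b, vv) in enumerate(segs):
            if vv <= 0:
                raise ValueError(
                    f"velocity segment {idx} ({a}:{b}) has non-positive velocity {vv}"
                )
            if a != cursor or b <= a:
                raise ValueError(
                    f"velocity segments must tile the lateral range; segment {idx} "
                    f"starts at {a}, expected {cursor}"
                )
            cursor = b
        if cursor != self.lateral_px:
            raise ValueError(
                f"velocity segments end at {cursor}, expected {self.lateral_px}"
            )
        return segs


@dataclass
class RawPhaseVolume:
    """Wrapped phase volume (depth x lateral x time) plus geometry.

    ``oracle_velocity`` has shape (depth, n_segments) and is present only
    for simulated data; real acquisitions carry ``None``.
    """

    phase: np.ndarray
    geometry: ScanGeometry
    oracle_velocity: np.ndarray | None = None
    oracle_segments: list[tuple[int, int]] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.phase.ndim != 3:
            raise ValueError(
                f"phase volume must be rank 3 (depth, lateral, time); got rank {self.phase.ndim}"
            )
        lo, hi = float(self.phase.min()), float(self.phase.max())
        if lo < -np.pi - 1e-6 or hi > np.pi + 1e-6:
            raise ValueError(f"phase values outside [-pi, pi]: range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.phase.shape


def _wave_packet(tau: np.ndarray, config: SimConfig) -> np.ndarray:
    """Gaussian-windowed cosine pulse, unit peak at tau = 0 (seconds)."""
    env = np.exp(-0.5 * (tau / config.pulse_sigma_s) ** 2)
    return env * np.cos(2.0 * np.pi * config.pulse_center_hz * tau)


def arrival_times(config: SimConfig, geometry: ScanGeometry) -> np.ndarray:
    """Cumulative wave arrival time (s) at each lateral pixel.

    For piecewise media the travel time integrates 1/v along the path,
    so the space-time ridge is continuous with slope 1/v(x) locally.
    """
    v_of_x = np.empty(config.lateral_px)
    for a, b, v in config.segments():
        v_of_x[a:b] = v
    arr = np.zeros(config.lateral_px)
    arr[1:] = np.cumsum(geometry.dx_m / v_of_x[:-1])
    return arr


def simulate_displacement(config: SimConfig, geometry: ScanGeometry | None = None) -> np.ndarray:
    """Axial displacement field (depth x lateral x time) in micrometres.

    Each rising edge of the square-wave excitation launches a wave packet
    whose arrival at lateral position x is delayed by the cumulative
    travel time; lateral and depth attenuation are exponential in
    physical distance.  The space-time argmax ridge of a noiseless field
    has slope 1/v(x) in physical units.
    """
    geometry = geometry or ScanGeometry()
    arr = arrival_times(config, geometry)

    t = np.arange(config.time_px) * geometry.dt_s
    period = 1.0 / config.excitation_hz
    delay = 3.0 * config.pulse_sigma_s if config.pulse_delay_s is None else config.pulse_delay_s
    if config.n_pulses is None:
        n_pulses = max(int(np.floor((t[-1] - delay) / period)) + 1, 1)
    else:
        n_pulses = int(config.n_pulses)

    wave = np.zeros((config.lateral_px, config.time_px))
    for k in range(n_pulses):
        tau = t[None, :] - delay - k * period - arr[:, None]
        wave += _wave_packet(tau, config)

    x_mm = np.arange(config.lateral_px) * geometry.lateral_um_per_px * 1e-3
    wave *= np.exp(-config.lateral_attenuation_per_mm * x_mm)[:, None]

    z_mm = np.arange(config.depth_px) * geometry.axial_um_per_px * 1e-3
    depth_env = np.exp(-config.depth_attenuation_per_mm * z_mm)
    # single-precision broadcast keeps full 512^3 volumes cheap
    return depth_env.astype(np.float32)[:, None, None] * wave.astype(np.float32)[None, :, :]


def _motion_term(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Common-mode phase disturbance m(t) from bulk sample motion."""
    t_px = config.time_px
    if config.motion_artifact == "none":
        return np.zeros(t_px)
    if config.motion_artifact == "drift":
        # slow breathing-like drift, total ramp <= pi over the window
        ramp = rng.uniform(0.2, 1.0) * np.pi
        return np.linspace(0.0, ramp, t_px) * rng.choice([-1.0, 1.0])
    # jump: up to 2 step discontinuities from involuntary movement
    m = np.zeros(t_px)
    for _ in range(rng.integers(1, 3)):
        at = rng.integers(1, t_px)
        m[at:] += rng.uniform(-np.pi, np.pi)
    return m


def displacement_to_phase(
    displacement: np.ndarray,
    geometry: ScanGeometry | None = None,
    config: SimConfig | None = None,
) -> RawPhaseVolume:
    """Encode a displacement field as wrapped interferometric phase.

    phase(z, x, t) = wrap(phi0(z, x) + c * d(z, x, t) + eps + m(t)) with
    a static speckle offset phi0 ~ U(-pi, pi) per A-line column, i.i.d.
    Gaussian phase noise eps, a motion term m(t), and c chosen so the
    peak modulation equals ``amplitude_rad``.  Fully reproducible from
    ``config.seed``.
    """
    geometry = geometry or ScanGeometry()
    config = config or SimConfig()
    d = np.asarray(displacement)
    if not np.all(np.isfinite(d)):
        raise ValueError("displacement field contains non-finite values")
    rng = np.random.default_rng(config.seed)

    nz, nx, nt = d.shape
    phi0 = rng.uniform(-np.pi, np.pi, size=(nz, nx)).astype(np.float32)
    dmax = float(np.abs(d).max())
    scale = config.amplitude_rad / dmax if dmax > 0 else 0.0

    # build and wrap in place: full-size volumes are ~0.5 GB in float32
    phase = np.multiply(d, np.float32(scale), dtype=np.float32)
    phase += phi0[:, :, None]
    if config.noise_sigma_rad > 0:
        noise = rng.standard_normal(d.shape, dtype=np.float32)
        noise *= np.float32(config.noise_sigma_rad)
        phase += noise
        del noise
    m = _motion_term(config, rng)
    if np.any(m):
        phase += m.astype(np.float32)[None, None, :]
    phase += np.float32(np.pi)
    np.mod(phase, np.float32(2 * np.pi), out=phase)
    phase -= np.float32(np.pi)

    segs = config.segments()
    oracle = np.tile([v for _, _, v in segs], (nz, 1)).astype(np.float32)
    return RawPhaseVolume(
        phase=phase,
        geometry=geometry,
        oracle_velocity=oracle,
        oracle_segments=[(a, b) for a, b, _ in segs],
    )


def simulate_volume(config: SimConfig, geometry: ScanGeometry | None = None) -> RawPhaseVolume:
    """Convenience: displacement simulation followed by phase encoding."""
    geometry = geometry or ScanGeometry()
    disp = simulate_displacement(config, geometry)
    vol = displacement_to_phase(disp, geometry, config)
    vol.source_id = f"sim-{config.seed}"
    return vol


@dataclass
class DatasetSplits:
    """Network-ready labelled slices, split by acquisition."""

    train: tuple[np.ndarray, np.ndarray, list[str]]
    val: tuple[np.ndarray, np.ndarray, list[str]]
    test: tuple[np.ndarray, np.ndarray, list[str]]

    def ids(self, part: str) -> set[str]:
        return set(getattr(self, part)[2])


def _oracle_label(config: SimConfig, lateral_offset: int, size: int) -> float:
    """Velocity of the segment covering the centre of the crop window."""
    centre = lateral_offset + size // 2
    for a, b, v in config.segments():
        if a <= centre < b:
            return v
    raise RuntimeError("crop centre outside velocity segments")  # pragma: no cover


def make_dataset(
    configs: Sequence[SimConfig],
    geometry: ScanGeometry | None = None,
    split: tuple[float, float, float] = (0.7, 0.15, 0.15),
    label_source: str = "oracle",
    slice_size: int = 48,
    seed: int = 0,
    crop_random: bool = False,
) -> DatasetSplits:
    """Simulate acquisitions and emit labelled train/val/test slices.

    Slices from any single simulated acquisition land in exactly one
    split (acquisition-level partitioning prevents leakage between
    training and evaluation).  Labels come either from the oracle
    velocity or from the conventional time-of-flight estimator run on
    the same volume (``label_source='tof'``).

    Crops are deterministic by default, mirroring the trigger-locked
    acquisition and fixed preprocessing window of the real system: the
    excitation is synchronous with the scan, so wave arrival times are
    reproducible across acquisitions and the network can anchor on
    them.  ``crop_random=True`` draws per-acquisition offsets instead.
    """
    if len(configs) == 0:
        raise ValueError("make_dataset needs at least one SimConfig")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if label_source not in ("oracle", "tof"):
        raise ValueError(f"unknown label_source {label_source!r}")
    geometry = geometry or ScanGeometry()
    rng = np.random.default_rng(seed)

    n = len(configs)
    order = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    assign = {}
    for rank, vol_idx in enumerate(order):
        if rank < n_train:
            assign[vol_idx] = "train"
        elif rank < n_train + n_val:
            assign[vol_idx] = "val"
        else:
            assign[vol_idx] = "test"

    from .preprocess import crop_volume, normalize_phase  # local: avoids cycle

    buckets = {p: ([], [], []) for p in ("train", "val", "test")}
    for vol_idx, cfg in enumerate(configs):
        vol = simulate_volume(cfg, geometry)
        max_lat = cfg.lateral_px - slice_size
        max_t = cfg.time_px - slice_size
        if crop_random:
            lat_off = int(rng.integers(0, max_lat + 1))
            t_off = int(rng.integers(0, max_t + 1))
        else:
            lat_off, t_off = 0, 0
        cropped = crop_volume(vol, lat_off, t_off, size=(slice_size, slice_size))

        if label_source == "oracle":
            labels = np.full(cfg.depth_px, _oracle_label(cfg, lat_off, slice_size))
            keep = np.ones(cfg.depth_px, dtype=bool)
        else:
            from .tof import profile_volume
            from .wavefield import displacement_pipeline

            disp, _ = displacement_pipeline(cropped.phase, geometry)
            profile = profile_volume(disp, geometry, max_layers=cfg.depth_px)
            labels = np.array([e.velocity_mps for e in profile.estimates])
            keep = np.array([e.converged for e in profile.estimates])

        source_id = f"vol{vol_idx:04d}"
        part = assign[vol_idx]
        xs, ys, ids = buckets[part]
        for z in range(cropped.phase.shape[0]):
            if not keep[z]:
                continue
            xs.append(normalize_phase(cropped.phase[z]).astype(np.float32))
            ys.append(labels[z])
            ids.append(source_id)

    def _stack(part):
        xs, ys, ids = buckets[part]
        if xs:
            x = np.stack(xs)[..., None].astype(np.float32)
            y = np.asarray(ys, dtype=np.float32)
        else:
            x = np.zeros((0, slice_size, slice_size, 1), np.float32)
            y = np.zeros((0,), np.float32)
        return x, y, ids

    return DatasetSplits(train=_stack("train"), val=_stack("val"), test=_stack("test"))
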