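"""Synthetic phantoms and raw-stream simulation for a scanning PARS /
autofluorescence microscope.

The simulator emulates a voice-coil stage that oscillates sinusoidally along
the fast axis while a second stage moves at constant velocity along the slow
axis, a pulsed excitation laser firing at a fixed repetition rate, and the
eight-channel digitizer stream the instrument records:

========  =====================================================
channel   contents
========  =====================================================
enc_a/b   AquadB quadrature encoder bits for the fast stage
trigger   one-sample-wide logic pulse per laser shot
pars      absorption-modulated interrogation burst (integrated
          downstream over a modulation window)
uv_refl   peak-held back-scattered excitation magnitude
af_*      peak-held autofluorescence magnitudes
          (collagen, NAD(P)H, FAD)
========  =====================================================

All analog channels may carry additive Gaussian read-out noise; encoder and
trigger channels are ideal binary signals.  Simulation is fully deterministic
for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: fast-axis forward traversal of the 2-bit Gray cycle
GRAY_CYCLE = ((0, 0), (0, 1), (1, 1), (1, 0))
_GRAY_A = np.array([s[0] for s in GRAY_CYCLE], dtype=np.uint8)
_GRAY_B = np.array([s[1] for s in GRAY_CYCLE], dtype=np.uint8)

#: names of the five ground-truth optical maps
MAP_NAMES = ("nuclear_absorption", "uv_scattering", "collagen_af", "nadh_af", "fad_af")

#: digitizer channel order
CHANNEL_NAMES = ("enc_a", "enc_b", "trigger", "pars", "uv_refl", "af_collagen", "af_nadh", "af_fad")

#: analog channel -> phantom map feeding it
CHANNEL_TO_MAP = {
    "pars": "nuclear_absorption",
    "uv_refl": "uv_scattering",
    "af_collagen": "collagen_af",
    "af_nadh": "nadh_af",
    "af_fad": "fad_af",
}

_HELD_CHANNELS = ("uv_refl", "af_collagen", "af_nadh", "af_fad")
#: first trigger placed here so a pre-trigger baseline always exists
_FIRST_TRIGGER_SAMPLE = 8


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition geometry and electronics settings.

    Parameters
    ----------
    fast_scan_distance:
        Peak-to-peak fast-axis travel in mm (instrument range 2-10 mm;
        smaller values are accepted for desk-scale phantoms).
    fast_frequency:
        Fast-stage oscillation frequency in Hz.
    slow_velocity:
        Constant slow-axis velocity in mm/s.
    prf:
        Laser pulse repetition frequency in Hz; must lie in the trigger
        generator range [1e4, 2e6] and below the sampling rate.
    duration:
        Record length in seconds.
    sample_rate:
        Digitizer rate in samples/s (default 50 MS/s, i.e. 20-ns interval).
    encoder_resolution:
        Fast-stage encoder pitch in um/count.
    pars_window:
        Modulation-window length in samples over which the PARS burst is
        integrated.
    hold_readout_offset:
        Sample offset after the trigger at which held channels are read;
        defaults to ``pars_window`` (the sample just before the peak-detector
        reset at ``trigger + pars_window + 1``).
    noise_sd:
        Additive Gaussian read-out noise on analog channels, as a fraction
        of that channel's full scale.
    pars_gain:
        Scale between the nuclear-absorption map value and the integrated
        PARS burst.
    trigger_jitter_sd:
        Optional trigger-timing jitter in samples (0 = ideal).
    seed:
        Seed for the noise generator.
    """

    fast_scan_distance: float = 2.0
    fast_frequency: float = 100.0
    slow_velocity: float = 0.1
    prf: float = 1.0e4
    duration: float = 1.0e-3
    sample_rate: float = 5.0e7
    encoder_resolution: float = 0.05
    pars_window: int = 16
    hold_readout_offset: int | None = None
    noise_sd: float = 0.01
    pars_gain: float = 1.0
    trigger_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fast_scan_distance", "fast_frequency", "slow_velocity", "prf",
                     "duration", "sample_rate", "encoder_resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScanConfig.{name} must be > 0, got {getattr(self, name)!r}")
        if not (1.0e4 <= self.prf <= 2.0e6):
            raise ValueError(f"ScanConfig.prf must lie in [1e4, 2e6] Hz, got {self.prf!r}")
        if self.prf >= self.sample_rate:
            raise ValueError(
                f"ScanConfig.prf ({self.prf}) must be below sample_rate ({self.sample_rate})")
        if self.pars_window < 4:
            raise ValueError(f"ScanConfig.pars_window must be >= 4 samples, got {self.pars_window}")
        if self.noise_sd < 0:
            raise ValueError(f"ScanConfig.noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def sample_interval(self) -> float:
        """Digitizer sampling interval in seconds."""
        return 1.0 / self.sample_rate

    @property
    def readout_offset(self) -> int:
        return self.pars_window if self.hold_readout_offset is None else self.hold_readout_offset

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScanConfig":
        return cls(**json.loads(text))


@dataclass
class SampleField:
    """Ground-truth 2-D optical maps of a phantom.

    Maps live on a common texel grid; texel ``(r, c)`` is centred at
    ``((c + 0.5) * resolution, (r + 0.5) * resolution)`` in um, with x the
    fast axis (width) and y the slow axis (height).
    """

    extent: tuple[float, float]  # (width, height) um
    resolution: float            # um / texel
    maps: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"SampleField.resolution must be > 0, got {self.resolution!r}")
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError(f"all maps must share one shape, got {shapes}")
        for name, m in self.maps.items():
            if np.any(m < 0):
                raise ValueError(f"map {name!r} contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.maps.values())).shape

    def lookup(self, name: str, x_um: np.ndarray, y_um: np.ndarray,
               blurred: dict[str, np.ndarray] | None = None) -> np.ndarray:
        """Bilinear map lookup at physical positions (um)."""
        m = (blurred or self.maps)[name]
        rows = np.asarray(y_um) / self.resolution - 0.5
        cols = np.asarray(x_um) / self.resolution - 0.5
        return ndimage.map_coordinates(m, [rows, cols], order=1, mode="nearest")


@dataclass
class RawRecord:
    """An eight-channel digitizer record plus acquisition metadata."""

    channels: dict[str, np.ndarray]
    sample_interval: float
    config: ScanConfig
    truth: dict[str, np.ndarray | float] | None = None

    def __post_init__(self) -> None:
        if tuple(self.channels) != CHANNEL_NAMES:
            raise ValueError(
                f"RawRecord requires exactly the 8 channels {CHANNEL_NAMES}, "
                f"got {tuple(self.channels)}")
        lengths = {len(c) for c in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"all channels must have equal length, got {lengths}")
        for name in ("enc_a", "enc_b", "trigger"):
            c = self.channels[name]
            if c.size and not np.isin(c, (0, 1)).all():
                raise ValueError(f"channel {name!r} must be binary valued")

    @property
    def n_samples(self) -> int:
        return len(self.channels["trigger"])

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w", track_order=True) as f:
            f.attrs["sample_interval"] = self.sample_interval
            f.attrs["scan_config"] = self.config.to_json()
            for name in CHANNEL_NAMES:
                data = self.channels[name]
                dtype = np.uint8 if name in ("enc_a", "enc_b", "trigger") else np.float32
                f.create_dataset(name, data=data.astype(dtype), track_times=False)
            if self.truth is not None:
                g = f.create_group("truth", track_order=True)
                for key in sorted(self.truth):
                    val = self.truth[key]
                    if np.isscalar(val):
                        g.attrs[key] = val
                    else:
                        g.create_dataset(key, data=np.asarray(val), track_times=False)

    @classmethod
    def from_hdf5(cls, path) -> "RawRecord":
        with h5py.File(path, "r") as f:
            channels = {name: f[name][...] for name in CHANNEL_NAMES}
            truth = None
            if "truth" in f:
                truth = {k: float(v) for k, v in f["truth"].attrs.items()}
                truth.update({k: f["truth"][k][...] for k in f["truth"]})
            return cls(
                channels=channels,
                sample_interval=float(f.attrs["sample_interval"]),
                config=ScanConfig.from_json(f.attrs["scan_config"]),
                truth=truth,
            )


# ---------------------------------------------------------------------------
# phantoms


def _require_positive(params: dict, *names: str) -> None:
    for name in names:
        if name in params and params[name] is not None and params[name] <= 0:
            raise ValueError(f"phantom parameter {name!r} must be > 0, got {params[name]!r}")


def generate_phantom(pattern: str, extent: tuple[float, float], resolution: float,
                     seed: int = 0, **params) -> SampleField:
    """Build a ground-truth :class:`SampleField` for a named test pattern.

    Patterns
    --------
    ``uniform``
        All five maps constant (``value``, default 1).
    ``edge``
        Half-plane step in every map (``edge_position`` um along
        ``axis`` in {'fast', 'slow'}; ``low``/``high`` levels).  Used for
        resolution characterization.
    ``gradient``
        Spatial step in the ground-truth optical redox ratio
        fad/(nadh+fad): ``orr_low`` below the split, ``orr_high`` above,
        at constant total autofluorescence ``intensity`` — an uncoupler-style
        metabolic perturbation along the ``axis`` (default 'slow').
    ``cells``
        ``n_cells`` cytoplasm disks (scattering + NAD(P)H + FAD) with
        nuclear disks (nuclear absorption) inside, on a smooth collagen
        background.
    ``checkerboard``
        Square tiles of alternating ``low``/``high`` in every map.
    """
    if extent[0] <= 0 or extent[1] <= 0:
        raise ValueError(f"phantom extent must be positive, got {extent!r}")
    if resolution <= 0:
        raise ValueError(f"phantom resolution must be > 0, got {resolution!r}")
    ny = max(1, int(round(extent[1] / resolution)))
    nx = max(1, int(round(extent[0] / resolution)))
    shape = (ny, nx)
    x = (np.arange(nx) + 0.5) * resolution
    y = (np.arange(ny) + 0.5) * resolution
    xx, yy = np.meshgrid(x, y)
    rng = np.random.default_rng(seed)

    if pattern == "uniform":
        value = params.get("value", 1.0)
        if value < 0:
            raise ValueError(f"phantom parameter 'value' must be >= 0, got {value!r}")
        maps = {name: np.full(shape, float(value)) for name in MAP_NAMES}

    elif pattern == "edge":
        axis = params.get("axis", "fast")
        pos = params.get("edge_position", extent[0 if axis == "fast" else 1] / 2.0)
        low = params.get("low", 0.0)
        high = params.get("high", 1.0)
        if axis not in ("fast", "slow"):
            raise ValueError(f"edge axis must be 'fast' or 'slow', got {axis!r}")
        coord = xx if axis == "fast" else yy
        step = np.where(coord >= pos, float(high), float(low))
        maps = {name: step.copy() for name in MAP_NAMES}

    elif pattern == "gradient":
        axis = params.get("axis", "slow")
        orr_low = params.get("orr_low", 0.4)
        orr_high = params.get("orr_high", 0.5)
        intensity = params.get("intensity", 1.0)
        split = params.get("split_position", extent[0 if axis == "fast" else 1] / 2.0)
        _require_positive(params, "intensity")
        for nm, v in (("orr_low", orr_low), ("orr_high", orr_high)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"phantom parameter {nm!r} must lie in [0, 1], got {v!r}")
        coord = xx if axis == "fast" else yy
        orr = np.where(coord >= split, float(orr_high), float(orr_low))
        maps = {
            "nuclear_absorption": np.full(shape, 0.3),
            "uv_scattering": np.full(shape, 0.5),
            "collagen_af": np.full(shape, 0.4),
            "nadh_af": intensity * (1.0 - orr),
            "fad_af": intensity * orr,
        }

    elif pattern == "cells":
        n_cells = int(params.get("n_cells", 10))
        cyto_radius = params.get("cyto_radius", min(extent) / 12.0)
        nucleus_radius = params.get("nucleus_radius", cyto_radius * 0.45)
        if n_cells <= 0:
            raise ValueError(f"phantom parameter 'n_cells' must be > 0, got {n_cells!r}")
        _require_positive(params, "cyto_radius", "nucleus_radius")
        maps = {name: np.zeros(shape) for name in MAP_NAMES}
        # smooth nonnegative collagen background
        bg = rng.normal(0.0, 1.0, shape)
        bg = ndimage.gaussian_filter(bg, sigma=max(2.0, 10.0 / resolution))
        rng_span = bg.max() - bg.min()
        maps["collagen_af"] = 0.15 + 0.25 * (bg - bg.min()) / (rng_span if rng_span else 1.0)
        centers = np.column_stack([
            rng.uniform(cyto_radius, extent[0] - cyto_radius, n_cells),
            rng.uniform(cyto_radius, extent[1] - cyto_radius, n_cells),
        ])
        jitter = rng.uniform(0.9, 1.1, n_cells)
        for (cx, cy), j in zip(centers, jitter):
            r2 = (xx - cx) ** 2 + (yy - cy) ** 2
            cyto = r2 <= cyto_radius ** 2
            nuc = r2 <= nucleus_radius ** 2
            maps["uv_scattering"][cyto] = 0.7 * j
            maps["nadh_af"][cyto] = 0.6 * j
            maps["fad_af"][cyto] = 0.4 * j
            maps["nuclear_absorption"][nuc] = 1.0 * j

    elif pattern == "checkerboard":
        period = params.get("period", min(extent) / 4.0)
        low = params.get("low", 0.2)
        high = params.get("high", 1.0)
        _require_positive(params, "period")
        tile = ((xx // period).astype(int) + (yy // period).astype(int)) % 2
        board = np.where(tile == 1, float(high), float(low))
        maps = {name: board.copy() for name in MAP_NAMES}

    else:
        raise ValueError(f"unknown phantom pattern {pattern!r}")

    return SampleField(extent=(nx * resolution, ny * resolution),
                       resolution=resolution, maps=maps)


# ---------------------------------------------------------------------------
# encoder / peak detector emulation


def encode_quadrature(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Emit AquadB channels for an integer position-count series.

    Forward increments traverse the Gray cycle 00 -> 01 -> 11 -> 10 -> 00;
    decrements reverse it.  Successive counts may differ by at most one
    (an encoder cannot skip a state between samples).
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be an integer series")
    if counts.size > 1:
        step = np.abs(np.diff(counts))
        if step.max(initial=0) > 1:
            i = int(np.argmax(step > 1))
            raise ValueError(
                f"count skip |delta|={int(step[i])} between samples {i} and {i + 1}: "
                "quadrature encoding cannot represent a skipped state")
    phase = np.mod(counts, 4)
    return _GRAY_A[phase].copy(), _GRAY_B[phase].copy()


def emulate_peak_hold(signal: np.ndarray, trigger_indices, reset_indices) -> np.ndarray:
    """Model an analog sample-and-hold peak detector.

    Between each trigger and its reset the output tracks the running maximum
    of ``signal`` since the trigger; outside hold windows the output sits at
    the 0 baseline.
    """
    signal = np.asarray(signal, dtype=float)
    trig = np.asarray(trigger_indices, dtype=int)
    rst = np.asarray(reset_indices, dtype=int)
    if trig.shape != rst.shape:
        raise ValueError("trigger_indices and reset_indices must pair one-to-one")
    held = np.zeros_like(signal)
    prev_end = -1
    for t, r in zip(trig, rst):
        if not (0 <= t < r <= signal.size):
            raise ValueError(f"hold window [{t}, {r}) does not fit the record")
        if t <= prev_end - 1:
            raise ValueError(f"hold window starting at {t} overlaps the previous window")
        held[t:r] = np.maximum.accumulate(signal[t:r])
        prev_end = r
    return held


# ---------------------------------------------------------------------------
# scan simulation


def _pars_burst_shape(window: int, decay: float) -> np.ndarray:
    """Damped half-cycle sinusoid, normalized to unit sample sum."""
    i = np.arange(window, dtype=float)
    shape = np.exp(-i / decay) * np.sin(np.pi * (i + 0.5) / window)
    return shape / shape.sum()


def _held_transient_shape(window: int) -> np.ndarray:
    """Fast rise/decay transient with unit peak (gamma-like, peak at i=2)."""
    i = np.arange(window, dtype=float)
    shape = (i / 2.0) * np.exp(1.0 - i / 2.0)
    return shape / shape.max()


def trajectory_positions(config: ScanConfig, field: SampleField,
                         t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """True stage positions (um, field frame) at times ``t`` (s).

    Fast axis: x(t) = W/2 + (D/2) sin(2 pi f t), centred on the field.
    Slow axis: y(t) = v t from the bottom edge.
    """
    d_um = config.fast_scan_distance * 1000.0
    x = field.extent[0] / 2.0 + (d_um / 2.0) * np.sin(2.0 * np.pi * config.fast_frequency * t)
    y = config.slow_velocity * 1000.0 * t
    return x, y


def simulate_scan(field: SampleField, config: ScanConfig,
                  psf_fwhm: float | dict[str, float] | None = None) -> RawRecord:
    """Simulate a full acquisition into a :class:`RawRecord`.

    Parameters
    ----------
    field:
        Ground-truth phantom.
    config:
        Scan geometry and electronics.
    psf_fwhm:
        Optional optical blur applied to the maps before sampling: a Gaussian
        point-spread FWHM in um, either one value for all channels or a dict
        keyed by map name.
    """
    d_um = config.fast_scan_distance * 1000.0
    if d_um > field.extent[0] + 1e-9:
        raise ValueError(
            f"fast-axis travel {d_um:g} um overshoots the field width "
            f"{field.extent[0]:g} um by {d_um - field.extent[0]:g} um")
    y_end = config.slow_velocity * 1000.0 * config.duration
    if y_end > field.extent[1] + 1e-9:
        raise ValueError(
            f"slow-axis travel {y_end:g} um overshoots the field height "
            f"{field.extent[1]:g} um by {y_end - field.extent[1]:g} um")

    n = int(round(config.duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    x_um, y_um = trajectory_positions(config, field, t)

    counts = np.round(x_um / config.encoder_resolution).astype(np.int64)
    if counts.size > 1 and np.abs(np.diff(counts)).max(initial=0) > 1:
        raise ValueError(
            "fast-axis count rate exceeds one count per sample; "
            "increase sample_rate or encoder_resolution")
    enc_a, enc_b = encode_quadrature(counts)

    # trigger times on the PRF comb, optionally jittered
    rng = np.random.default_rng(config.seed)
    n_pulses = int(np.ceil(n / (config.sample_rate / config.prf))) + 1
    idx = _FIRST_TRIGGER_SAMPLE + np.round(
        np.arange(max(n_pulses, 0)) * config.sample_rate / config.prf).astype(np.int64)
    if config.trigger_jitter_sd > 0:
        idx = idx + np.round(rng.normal(0, config.trigger_jitter_sd, idx.size)).astype(np.int64)
        idx = np.unique(np.clip(idx, _FIRST_TRIGGER_SAMPLE, n - config.pars_window - 3))
    idx = idx[idx + config.pars_window + 2 <= n]

    trigger = np.zeros(n, dtype=np.uint8)
    trigger[idx] = 1

    # optional optical blur of the ground-truth maps
    blurred = None
    if psf_fwhm is not None:
        fwhm_of = (psf_fwhm if isinstance(psf_fwhm, dict)
                   else {name: float(psf_fwhm) for name in MAP_NAMES})
        blurred = {}
        for name in MAP_NAMES:
            w = fwhm_of.get(name, 0.0)
            sigma = w / (2.0 * np.sqrt(2.0 * np.log(2.0))) / field.resolution
            blurred[name] = (ndimage.gaussian_filter(field.maps[name], sigma)
                             if sigma > 0 else field.maps[name])

    px, py = x_um[idx], y_um[idx]
    values = {name: field.lookup(name, px, py, blurred) for name in MAP_NAMES}

    window = config.pars_window
    burst = _pars_burst_shape(window, decay=window / 3.0)
    transient = _held_transient_shape(window)
    resets = idx + window + 1

    pars = np.zeros(n)
    pars_amp = values["nuclear_absorption"] * config.pars_gain
    for k, i0 in enumerate(idx):
        pars[i0:i0 + window] += pars_amp[k] * burst

    channels: dict[str, np.ndarray] = {
        "enc_a": enc_a, "enc_b": enc_b, "trigger": trigger, "pars": pars,
    }
    for ch in _HELD_CHANNELS:
        raw = np.zeros(n)
        amp = values[CHANNEL_TO_MAP[ch]]
        for k, i0 in enumerate(idx):
            raw[i0:i0 + window] = amp[k] * transient
        channels[ch] = emulate_peak_hold(raw, idx, resets)

    # digitizer read-out noise on analog channels only
    if config.noise_sd > 0:
        for ch in ("pars", *_HELD_CHANNELS):
            full_scale = np.abs(channels[ch]).max()
            if full_scale == 0:
                full_scale = 1.0
            channels[ch] = channels[ch] + rng.normal(0, config.noise_sd * full_scale, n)
    for ch in ("pars", *_HELD_CHANNELS):
        channels[ch] = channels[ch].astype(np.float32)

    truth: dict[str, np.ndarray | float] = {
        "pulse_indices": idx,
        "pulse_x_um": px,
        "pulse_y_um": py,
        "x0_um": float(x_um[0]) if n else field.extent[0] / 2.0,
        "y0_um": float(y_um[0]) if n else 0.0,
    }
    for name in MAP_NAMES:
        truth[f"value_{name}"] = values[name]

    logger.info("simulated %d samples, %d pulses", n, idx.size)
    return RawRecord(channels=channels, sample_interval=config.sample_interval,
                     config=config, truth=truth)
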