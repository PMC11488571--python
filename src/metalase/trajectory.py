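"""Stage-trajectory reconstruction from the raw digitizer stream.

Fast-axis positions are decoded incrementally from the two AquadB quadrature
channels; slow-axis positions follow from sample timestamps and the known
constant stage velocity.  The position origin is the first sample — images
are registered to reconstructed coordinates, so only relative accuracy
matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition_sim import RawRecord

# Gray state (a*2 + b) -> phase index on the forward cycle 00,01,11,10
_PHASE_LUT = np.array([0, 1, 3, 2], dtype=np.int64)


@dataclass
class TrajectoryTable:
    """Per-sample stage positions in um, origin at the first sample."""

    fast_um: np.ndarray
    slow_um: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.fast_um)


def decode_quadrature(enc_a: np.ndarray, enc_b: np.ndarray,
                      encoder_resolution: float,
                      tolerate_glitches: bool = False) -> np.ndarray:
    """Decode AquadB channels into fast-axis positions (um).

    Each legal transition moves one step along the 2-bit Gray cycle
    (+1 forward, -1 backward, 0 for no change).  A transition in which both
    bits flip is physically unobservable and raises, unless
    ``tolerate_glitches`` is set, in which case it is treated as no movement.
    """
    a = np.asarray(enc_a).astype(np.int64)
    b = np.asarray(enc_b).astype(np.int64)
    if a.shape != b.shape:
        raise ValueError("enc_a and enc_b must have equal length")
    if a.size == 0:
        return np.zeros(0)
    phase = _PHASE_LUT[a * 2 + b]
    dphase = np.mod(np.diff(phase), 4)
    illegal = dphase == 2
    if illegal.any():
        i = int(np.flatnonzero(illegal)[0])
        if not tolerate_glitches:
            raise ValueError(
                f"illegal quadrature transition (both bits flip) at sample {i + 1}")
        dphase = dphase.copy()
        dphase[illegal] = 0
    step = np.where(dphase == 1, 1, np.where(dphase == 3, -1, 0))
    counts = np.concatenate([[0], np.cumsum(step)])
    return counts * encoder_resolution


def reconstruct_trajectory(record: RawRecord,
                           tolerate_glitches: bool = False) -> TrajectoryTable:
    """Per-sample fast/slow positions for a record.

    fast(i) from quadrature decoding; slow(i) = slow_velocity * i * dt.
    """
    cfg = record.config
    fast = decode_quadrature(record.channels["enc_a"], record.channels["enc_b"],
                             cfg.encoder_resolution, tolerate_glitches)
    n = len(fast)
    slow = cfg.slow_velocity * 1000.0 * np.arange(n) * record.sample_interval
    return TrajectoryTable(fast_um=fast, slow_um=slow, valid=np.ones(n, dtype=bool))


def detect_triggers(trigger: np.ndarray) -> np.ndarray:
    """Sample indices of 0 -> 1 transitions of the trigger channel."""
    t = np.asarray(trigger).astype(np.int64)
    if t.size == 0:
        return np.zeros(0, dtype=np.int64)
    return np.flatnonzero((t[1:] == 1) & (t[:-1] == 0)) + 1
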