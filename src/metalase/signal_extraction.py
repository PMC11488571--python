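"""Per-pulse optical-value extraction from a raw record.

For every laser trigger the PARS channel is integrated over the modulation
window (with optional pre-trigger baseline subtraction) and each peak-held
channel is read once, just before the analog peak detectors are reset.
The result is one event row per pulse: time, reconstructed stage position,
and the five optical values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition_sim import RawRecord
from .trajectory import TrajectoryTable, detect_triggers

logger = logging.getLogger(__name__)

#: exact on-disk column order of the event table
EVENT_COLUMNS = ("pulse_index", "t_s", "x_um", "y_um",
                 "pars", "uv_refl", "af_collagen", "af_nadh", "af_fad")
VALUE_COLUMNS = ("pars", "uv_refl", "af_collagen", "af_nadh", "af_fad")

#: samples ahead of each trigger averaged for the PARS baseline
_BASELINE_SAMPLES = 4


@dataclass
class PulseEventTable:
    """One row per laser pulse; wraps a pandas DataFrame."""

    df: pd.DataFrame
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(EVENT_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"event table missing columns {sorted(missing)}")
        self.df = self.df.loc[:, list(EVENT_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> np.ndarray:
        return self.df[["x_um", "y_um"]].to_numpy()

    def to_csv(self, path) -> None:
        # %.17g guarantees exact float64 round-trip, so re-gridding a saved
        # table is bit-reproducible (triangulations are sensitive to ulps)
        self.df.to_csv(path, index=False, lineterminator="\n",
                       float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "PulseEventTable":
        return cls(df=pd.read_csv(path))


def extract_pulse_values(record: RawRecord, trajectory: TrajectoryTable,
                         pulse_indices: np.ndarray | None = None,
                         baseline_subtract: bool = True) -> PulseEventTable:
    """Build the per-pulse event table.

    PARS value: plain sample sum over ``[trigger, trigger + pars_window)``
    minus ``pars_window`` times the mean of the 4 samples preceding the
    trigger (AC-coupling emulation; disable with ``baseline_subtract=False``).
    Held channels are read at ``trigger + hold_readout_offset``.  Positions
    come from the trajectory at the trigger sample.  Pulses whose window
    exceeds the record end are dropped and counted.
    """
    cfg = record.config
    if pulse_indices is None:
        pulse_indices = detect_triggers(record.channels["trigger"])
    idx = np.asarray(pulse_indices, dtype=np.int64)
    if len(trajectory) != record.n_samples:
        raise ValueError("trajectory length does not match record length")

    window = cfg.pars_window
    offset = cfg.readout_offset
    last_needed = np.maximum(window, offset + 1)
    keep = (idx + last_needed <= record.n_samples) & (idx >= 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d pulses whose window exceeds the record", n_dropped)
    idx = idx[keep]

    pars = np.asarray(record.channels["pars"], dtype=np.float64)
    starts = idx[:, None] + np.arange(window)[None, :]
    pars_vals = pars[starts].sum(axis=1)
    if baseline_subtract:
        base = idx[:, None] - np.arange(1, _BASELINE_SAMPLES + 1)[None, :]
        base = np.clip(base, 0, record.n_samples - 1)
        pars_vals = pars_vals - window * pars[base].mean(axis=1)

    data = {
        "pulse_index": np.arange(idx.size, dtype=np.int64),
        "t_s": idx * record.sample_interval,
        "x_um": trajectory.fast_um[idx],
        "y_um": trajectory.slow_um[idx],
        "pars": pars_vals,
    }
    for ch in ("uv_refl", "af_collagen", "af_nadh", "af_fad"):
        data[ch] = np.asarray(record.channels[ch], dtype=np.float64)[idx + offset]

    return PulseEventTable(df=pd.DataFrame(data), n_dropped=n_dropped,
                           meta={"baseline_subtract": baseline_subtract})
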