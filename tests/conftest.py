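import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metalase.signal_extraction import VALUE_COLUMNS, PulseEventTable

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def make_events(x, y, value_fn=None, values=None) -> PulseEventTable:
    """Event table at positions (x, y) with all five channels set either by
    ``value_fn(x, y)`` or per-channel from ``values`` (dict)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    df = pd.DataFrame({
        "pulse_index": np.arange(x.size),
        "t_s": np.arange(x.size) * 1e-5,
        "x_um": x,
        "y_um": y,
    })
    for name in VALUE_COLUMNS:
        if values is not None:
            df[name] = np.asarray(values[name], dtype=float)
        else:
            df[name] = value_fn(x, y)
    return PulseEventTable(df=df)


@pytest.fixture(scope="session")
def small_record():
    """A small noise-free simulated record over a checkerboard phantom,
    shared by extraction/trajectory tests."""
    from metalase import ScanConfig, generate_phantom, simulate_scan

    field = generate_phantom("checkerboard", (60.0, 20.0), 0.25,
                             period=10.0, low=0.2, high=1.0)
    cfg = ScanConfig(fast_scan_distance=0.05, fast_frequency=50.0,
                     slow_velocity=0.05, prf=2.0e4, duration=0.24,
                     sample_rate=1.0e6, noise_sd=0.0, seed=42)
    return simulate_scan(field, cfg), field, cfg
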