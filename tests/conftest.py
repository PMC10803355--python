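import numpy as np
import pandas as pd
import pytest

from secsim.microsim import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_params():
    """Abbreviated run lengths for fast end-to-end tests."""
    return SimParams(duration=240.0, warmup=60.0)


def make_records(speed_blocks, vehicle_ids=None):
    """Trajectory frame from (speed_kmh, n_samples) blocks, one per vehicle.

    Each sample represents one second of travel, so a block contributes
    speed * n / 3600 vehicle-km of distance.
    """
    frames = []
    for k, (v, n) in enumerate(speed_blocks):
        vid = vehicle_ids[k] if vehicle_ids else k
        frames.append(
            pd.DataFrame(
                {
                    "vehicle_id": vid,
                    "time_s": np.arange(n, dtype=float),
                    "position_m": np.cumsum(np.full(n, v / 3.6)),
                    "speed_kmh": float(v),
                    "lane": 0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
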