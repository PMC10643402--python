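import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dmmn.preprocess import TrialAlignedResponses

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_aligned(values, frame_rate=30.0, baseline_frames=5, roles=None,
                 durations=None, prev_durations=None, soa=0.55):
    """Build a TrialAlignedResponses directly from a values matrix."""
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    offsets = np.arange(-baseline_frames, f - baseline_frames)
    md = pd.DataFrame({
        "role": roles if roles is not None else ["standard"] * n,
        "duration_ms": durations if durations is not None else [50.0] * n,
        "frequency_hz": [2000.0] * n,
        "prev_duration_ms": (prev_durations if prev_durations is not None
                             else [50.0] * n),
        "onset_s": np.arange(n) * soa,
        "photostim": [False] * n,
        "block_position": [None] * n,
        "event_index": np.arange(n),
    })
    return TrialAlignedResponses(values, offsets, frame_rate, md,
                                 baseline_frames)
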