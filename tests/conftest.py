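import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture
def small_trace():
    """Hand-built 2-section trace with one excursion on each side.

    s_path steps by 10 m; lane threshold 0.85 m with the default geometry,
    so |lat| = 1.0 invades.
    """
    from vergedrive.driving import DrivingTrace

    df = pd.DataFrame({
        "t": np.arange(12, dtype=float),
        "s_path": 10.0 * np.arange(12),
        "speed": 36.0,
        "lat_offset": [0, 1.0, 1.0, 0, -1.0, 0,   # dual carriageway
                       0, 1.0, 0, -1.0, -1.0, 0],  # mountain road
        "section": ["dual_carriageway"] * 6 + ["mountain_road"] * 6,
    })
    return DrivingTrace(df)
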