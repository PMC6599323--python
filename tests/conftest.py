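import numpy as np
import pytest

from fermkin import (
    FPS_PARAMS,
    WT_PARAMS,
    NoiseSpec,
    generate,
)


@pytest.fixture
def wt_params():
    return WT_PARAMS


@pytest.fixture
def fps_params():
    return FPS_PARAMS


@pytest.fixture
def daily_times():
    return np.arange(0.0, 13.0)


@pytest.fixture
def noiseless_wt_daily(wt_params, daily_times):
    """Noiseless daily WT trajectory: the canonical recovery fixture."""
    return generate(wt_params, daily_times, NoiseSpec(kind="none"))
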