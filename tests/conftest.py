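import numpy as np
import pytest

from mrpool.tissue import ExchangeMatrix, PoolSpec, TissueModel, preset_model


@pytest.fixture
def water():
    """Single free water pool, T1/T2 = 1 s / 80 ms."""
    return TissueModel((PoolSpec("water", "free", 1.0, 1.0, 0.080),),
                       ExchangeMatrix(np.zeros((1, 1))))


@pytest.fixture
def slow_water():
    """Single pool with negligible relaxation, for pure-rotation checks."""
    return TissueModel((PoolSpec("water", "free", 1.0, 1e4, 1e4),),
                       ExchangeMatrix(np.zeros((1, 1))))


@pytest.fixture(params=["mwf_two_pool", "qmt_two_pool",
                        "gagcest_three_pool", "mt_fat_three_pool"])
def preset(request):
    return preset_model(request.param)
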