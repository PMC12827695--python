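import numpy as np
import pytest

from edgedyn.ets import RoiTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_series(rng):
    """Small random subject: 6 ROIs x 80 frames."""
    data = rng.normal(size=(6, 80))
    return RoiTimeSeries(
        subject_id="subA",
        data=data,
        roi_labels=tuple(f"r{i}" for i in range(6)),
        tr_seconds=3.0,
    )


def make_series(data, tr=1.0, sid="s"):
    data = np.asarray(data, dtype=float)
    return RoiTimeSeries(
        subject_id=sid,
        data=data,
        roi_labels=tuple(f"r{i}" for i in range(data.shape[0])),
        tr_seconds=tr,
    )
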