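import numpy as np
import pytest

from oxiscale import SpO2Series


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_series(values, mask=None, dt=1.0, scale=1, subject="t"):
    return SpO2Series(subject_id=subject, values=np.asarray(values, dtype=float),
                      valid_mask=mask, dt_s=dt, scale_s=scale)


@pytest.fixture
def series_factory():
    return make_series
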