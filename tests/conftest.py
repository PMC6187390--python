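import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from actimetry import MinuteAISeries

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

NOON = pd.Timestamp("2018-05-09 12:00:00")


def minutes_from_values(values, start=NOON, epochs_per_minute=12) -> MinuteAISeries:
    values = np.asarray(values, dtype=float)
    idx = pd.DatetimeIndex(start + pd.to_timedelta(np.arange(len(values)), unit="min"))
    return MinuteAISeries(idx, values, epochs_per_minute=epochs_per_minute)


@pytest.fixture
def noon() -> pd.Timestamp:
    return NOON


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180509)
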