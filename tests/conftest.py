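"""Shared fixtures: small on-grid sensor series and a fast scenario."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dielsense.signals import SensorMeta, SensorSeries
from dielsense.synth import ScenarioConfig


def make_series(values, organ: str = "fruit", start: str = "2018-01-10 00:00") -> SensorSeries:
    """Wrap raw values in a SensorSeries on the 15-min grid."""
    values = np.asarray(values, dtype=float)
    index = pd.date_range(start, periods=len(values), freq="15min")
    return SensorSeries(values=pd.Series(values, index=index), meta=SensorMeta(organ=organ))


@pytest.fixture
def full_day_index() -> pd.DatetimeIndex:
    """One complete calendar day on the 15-min grid (96 slots)."""
    return pd.date_range("2018-01-10 00:00", periods=96, freq="15min")


@pytest.fixture
def fast_scenario() -> ScenarioConfig:
    """Default study-layout scenario at the package's default seed."""
    return ScenarioConfig(seed=0)
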