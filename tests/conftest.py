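import numpy as np
import pandas as pd
import pytest

from aedes_capacity import LifeHistoryParams, TemperatureSeries, TrapConfig


@pytest.fixture(scope="session")
def params() -> LifeHistoryParams:
    return LifeHistoryParams()


@pytest.fixture(scope="session")
def trap16() -> TrapConfig:
    return TrapConfig(n_traps=16, n_households=8000)


@pytest.fixture
def constant_forcing():
    """Factory for a constant-temperature daily forcing series."""

    def make(t_kelvin: float, n_days: int = 730) -> TemperatureSeries:
        dates = pd.date_range("2008-01-01", periods=n_days, freq="D")
        return TemperatureSeries(
            dates=dates, values=np.full(n_days, t_kelvin), unit="K"
        )

    return make
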