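import numpy as np
import pytest

from pyrocycle.synthetic import fixture_savanna_decline, savanna_truth
from pyrocycle.types import ForcingSeries, MetRecord, PoolState


@pytest.fixture(scope="session")
def savanna_params():
    return savanna_truth()


@pytest.fixture
def met():
    return MetRecord(t_mean=25.0, precip=80.0, sw_rad=20.0, days=30.0)


@pytest.fixture
def pools():
    return PoolState(labile=20.0, foliar=100.0, fine_root=120.0, wood=800.0,
                     litter=150.0, som=5000.0, water=100.0)


def constant_forcing(n_months: int, ba: float = 0.02, start_year: int = 2001,
                     t_mean: float = 25.0, precip: float = 80.0,
                     sw_rad: float = 20.0) -> ForcingSeries:
    return ForcingSeries(
        t_mean=np.full(n_months, t_mean),
        precip=np.full(n_months, precip),
        sw_rad=np.full(n_months, sw_rad),
        days=np.full(n_months, 30.0),
        ba_frac=np.full(n_months, ba),
        start_year=start_year,
    )


@pytest.fixture
def small_forcing():
    return constant_forcing(24)


@pytest.fixture(scope="session")
def fixture_bundle():
    return fixture_savanna_decline()
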