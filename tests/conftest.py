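import numpy as np
import pandas as pd
import pytest

from dendrogwas.io_core import RingSeries
from dendrogwas.synthetic_data import SimConfig, simulate_all


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(tree_id="T1", core_id="c1", provenance="P01", years=None, rw=None, **extra):
    years = np.asarray(years if years is not None else range(2000, 2010))
    rw = np.asarray(rw if rw is not None else np.ones(len(years)), dtype=float)
    data = {"RW": rw}
    data.update({k: np.asarray(v, dtype=float) for k, v in extra.items()})
    return RingSeries(tree_id=tree_id, core_id=core_id, provenance=provenance, years=years, data=data)


@pytest.fixture
def small_sim():
    """One cached small synthetic dataset shared across tests."""
    cfg = SimConfig(
        seed=7,
        n_provenances=4,
        trees_per_provenance=(12, 12, 12, 12),
        n_markers=80,
        causal_r2=(0.3,),
    )
    return simulate_all(cfg)


@pytest.fixture
def site_monthly_precip():
    """A plain gamma monthly precipitation series over 1961-2011."""
    gen = np.random.default_rng(5)
    years = np.arange(1961, 2012)
    idx = pd.MultiIndex.from_product([years, range(1, 13)], names=["year", "month"])
    return pd.Series(gen.gamma(2.0, 30.0, size=len(idx)), index=idx)
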