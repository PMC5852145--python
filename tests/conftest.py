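import numpy as np
import pytest

from conefit.dataset import Dataset
from conefit.model import ConditionParams, PeripheralParams
from conefit.preprocess import MpTimeSeries
from conefit.priors import PriorSet, TruncatedNormalPrior, default_priors
from conefit.synth import (
    NoiseSpec,
    SyntheticDatasetSpec,
    default_generating_core,
    default_generating_topology,
    generate_dataset,
)


@pytest.fixture(scope="session")
def m7():
    return default_generating_topology()


@pytest.fixture(scope="session")
def gen_theta():
    return default_generating_core()


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def small_m7_dataset():
    """6-series M_7 dataset, short traces, white noise only: fast fixture."""
    spec = SyntheticDatasetSpec(
        design=(("control", 2), ("DNDS", 2), ("STX", 2)),
        series_length_s=300,
        noise=NoiseSpec(spike_rate=0.0, step_probability=0.0),
        seed=11,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def default_m7_dataset():
    """Full 16-series dataset emulating the 10 uM design, all noise types."""
    return generate_dataset(SyntheticDatasetSpec(seed=7))


def toy_series(values, sigma=1.0, series_id="toy", label="control"):
    return MpTimeSeries(series_id=series_id, condition_label=label,
                        values=np.asarray(values, dtype=float), sigma_i=sigma)


def flat_dataset(rng, n_series=2, T=50, sigma=1.0, v0=-75.0):
    """Series that are pure baseline + white noise (fit by any topology)."""
    series, conds = [], []
    for i in range(n_series):
        v = v0 + rng.normal(0.0, sigma, T)
        series.append(toy_series(v, sigma=sigma, series_id=f"flat{i}"))
        conds.append(ConditionParams(S_max=0.0))
    return Dataset(series=series, conditions=conds)
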