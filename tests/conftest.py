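"""Shared synthetic datasets and fits (session-scoped: the generators are
deterministic, so reuse across tests is safe and keeps the suite fast)."""

import pytest

from rbale import synthetic_data as sd
from rbale.estimation import RbaleFitConfig, fit_rbale


@pytest.fixture(scope="session")
def ds_constant_noiseless():
    return sd.gen_rbale_dataset(sd.glucose_validation(seed=1, cv=0.0))


@pytest.fixture(scope="session")
def ds_constant_noisy():
    return sd.gen_rbale_dataset(sd.glucose_validation(seed=7, cv=0.02))


@pytest.fixture(scope="session")
def ds_switching_noisy():
    return sd.gen_rbale_dataset(sd.ethanol_evolution_r3(seed=3, cv=0.02))


@pytest.fixture(scope="session")
def ds_bioreactor_noiseless():
    return sd.gen_bioreactor_dataset(sd.bioreactor_lab_scale(seed=2, cv=0.0))


@pytest.fixture(scope="session")
def ds_bioreactor_noisy():
    return sd.gen_bioreactor_dataset(sd.bioreactor_lab_scale(seed=2, cv=0.03))


@pytest.fixture(scope="session")
def fit_constant_noiseless(ds_constant_noiseless):
    ds = ds_constant_noiseless
    return fit_rbale(ds.timeseries, ds.events, RbaleFitConfig(n_starts=2))


@pytest.fixture(scope="session")
def fit_constant_noisy(ds_constant_noisy):
    ds = ds_constant_noisy
    return fit_rbale(ds.timeseries, ds.events)


@pytest.fixture(scope="session")
def fit_switching_noisy(ds_switching_noisy):
    ds = ds_switching_noisy
    return fit_rbale(ds.timeseries, ds.events)
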