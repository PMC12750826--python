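import numpy as np
import pytest

from ioneff.compounds import aggregate_measurements
from ioneff.synthetic import (
    SimulationConfig,
    simulate_compounds,
    simulate_ie,
    simulate_spectra,
)
from ioneff.workflows import train_cnl_workflow, train_fp_workflow

RECOVERY_SEED = 11


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=RECOVERY_SEED, n_compounds=30)


@pytest.fixture(scope="session")
def small_compounds(small_config):
    return simulate_compounds(small_config)


@pytest.fixture(scope="session")
def recovery_config():
    # planted-coefficient recovery conditions: ~500 CNL rows, sd 0.1
    return SimulationConfig(
        seed=RECOVERY_SEED, n_compounds=125, spectra_per_compound=2,
        ie_noise_sd=0.1,
    )


@pytest.fixture(scope="session")
def recovery_dataset(recovery_config):
    compounds = simulate_compounds(recovery_config)
    entries = aggregate_measurements(simulate_ie(compounds, recovery_config))
    sim = simulate_spectra(compounds, recovery_config)
    return compounds, entries, sim


@pytest.fixture(scope="session")
def cnl_result(recovery_dataset):
    _, entries, sim = recovery_dataset
    return train_cnl_workflow(entries, sim.spectra, seed=1)


@pytest.fixture(scope="session")
def fp_result(recovery_dataset):
    _, entries, _ = recovery_dataset
    return train_fp_workflow(entries, seed=1)


@pytest.fixture(scope="session")
def noiseless_dataset():
    config = SimulationConfig(
        seed=RECOVERY_SEED, n_compounds=125, spectra_per_compound=2,
        ie_noise_sd=0.0, mass_jitter_sd=0.0, noise_fragment_rate=0.0,
    )
    compounds = simulate_compounds(config)
    entries = aggregate_measurements(simulate_ie(compounds, config))
    sim = simulate_spectra(compounds, config)
    return compounds, entries, sim


@pytest.fixture
def rng():
    return np.random.default_rng(0)
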