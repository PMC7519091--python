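import numpy as np
import pytest

from isomix.bayes_fit import McmcSettings
from isomix.kinetics import CompartmentParams
from isomix.synthetic_data import ExperimentDesign, simulate_feeding_trial


@pytest.fixture
def small_settings():
    """Scaled-down MCMC settings for contract-level tests."""
    return McmcSettings(n_chains=3, n_iter=4000, n_burn=2000, thin=2, seed=123)


@pytest.fixture
def trial_params_g1():
    """Generating values for one muscle-carbon trajectory."""
    return {
        (1, "muscle", "c"): CompartmentParams(-22.83, -19.23, 0.20),
        (1, "muscle", "n"): CompartmentParams(8.71, 10.41, 0.05),
    }


@pytest.fixture
def noisy_g1_samples(trial_params_g1):
    design = ExperimentDesign(noise_sd_c=0.3, noise_sd_n=0.3, seed=42)
    return simulate_feeding_trial(trial_params_g1, design)


@pytest.fixture
def clean_g1_samples(trial_params_g1):
    design = ExperimentDesign(noise_sd_c=0.0, noise_sd_n=0.0, seed=42)
    return simulate_feeding_trial(trial_params_g1, design)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
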