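import numpy as np
import pytest

from ca1ripple.params import (
    DendriteParams,
    PeakCurrentDistribution,
    default_e_params,
    default_i_params,
)


@pytest.fixture(scope="session")
def e_params():
    return default_e_params()


@pytest.fixture(scope="session")
def e_params_quiet(e_params):
    """Calibrated E membrane with noise off (single-neuron protocols)."""
    d = e_params.to_dict()
    d["noise_strength"] = 0.0
    from ca1ripple.params import NeuronPopulationParams

    return NeuronPopulationParams(**d)


@pytest.fixture(scope="session")
def dendrite():
    return DendriteParams()


@pytest.fixture(scope="session")
def small_model3_config():
    """Scaled-down model-3 network preserving all mean in-degrees."""
    from ca1ripple.experiments import ExperimentConfig

    n_e = 3000
    return ExperimentConfig(
        variant="model3", n_e=n_e, n_i=200,
        p_ee=197.0 / n_e, p_ei=0.4,
        dt=0.02, n_realizations=2, master_seed=11,
    )
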