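import numpy as np
import pytest

from dnfreach.architecture import ModelConfig, init_model
from dnfreach.config import child_seeds
from dnfreach.tasks import SessionConfig, run_session

MASTER_SEED = 20121115


@pytest.fixture(scope="session")
def base_config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def quiet_config() -> ModelConfig:
    """Noise-free variant of the default model (deterministic dynamics)."""
    from dataclasses import replace
    return replace(ModelConfig(), spatial_q=0.0, node_q=0.0, assoc_q=0.0,
                   prep_q=0.0, motor_q=0.0)


@pytest.fixture(scope="session")
def trained(base_config):
    """IR-trained two-context model (1000 trials, 80% inferred, cardinal
    cues) plus its training log; shared by the behavioral test groups."""
    s_init, s_sess = child_seeds(MASTER_SEED, 2)
    model = init_model(base_config, np.random.default_rng(s_init))
    model, results = run_session(
        model, SessionConfig.ir_training(n_trials=1000, seed=s_sess))
    return model, results


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
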