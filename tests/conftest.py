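import numpy as np
import pytest

from fraccum.train import collect_cumulant_samples, train_sign_maps

#: reduced-scale training protocol shared by the training-dependent tests:
#: 200 two-node simulations, connection weight 0.9, 60 s at 200 Hz
TRAIN_N_SIMS = 200
TRAIN_DURATION = 60.0
TRAIN_WEIGHT = 0.9


@pytest.fixture(scope="session")
def rng_factory():
    def make(seed):
        return np.random.default_rng(seed)

    return make


@pytest.fixture(scope="session")
def training_samples():
    """Cumulant maps from the reduced training run (seeded, cached per session)."""
    rng = np.random.default_rng(1234)
    return collect_cumulant_samples(
        TRAIN_N_SIMS, TRAIN_WEIGHT, rng, duration=TRAIN_DURATION
    )


@pytest.fixture(scope="session")
def trained_maps(training_samples):
    return train_sign_maps(samples=training_samples, weight=TRAIN_WEIGHT)
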