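import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def flat_params():
    """Flat equal-baseline, decay-free melt model: the derivative peak of
    this curve coincides exactly with the thermodynamic midpoint."""
    from shiftscan.synthetic import SyntheticMeltParams

    def make(tm=60.0, noise_sd=0.0, seed=0):
        return SyntheticMeltParams(
            tm_true=tm, noise_sd=noise_sd, decay_rate=0.0,
            native_baseline=(1.0, 0.0), unfolded_baseline=(3.0, 0.0),
            seed=seed)

    return make
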