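import numpy as np
import pytest

from heatadapt.synthetic import HRTGroundTruth, generate_hrt_series


@pytest.fixture
def noiseless_truth():
    """Deterministic visit template: no noise, plateau out of reach in 45 min."""
    return HRTGroundTruth(
        noise_sd={"tgi": 0.0, "tsk": 0.0, "hr": 0.0, "lsr": 0.0}, lsr_plateau=5.0
    )


@pytest.fixture
def noiseless_series(noiseless_truth):
    return generate_hrt_series(noiseless_truth, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
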