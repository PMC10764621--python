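import numpy as np
import pytest

from sanpace import APGroundTruth, generate_ap_train


@pytest.fixture(scope="session")
def noiseless_gt():
    return APGroundTruth(noise_sd_mV=0.0)


@pytest.fixture(scope="session")
def noiseless_train(noiseless_gt):
    """10 s noiseless default AP train with per-cycle ground truth."""
    trace, truth = generate_ap_train(noiseless_gt, duration_s=10.0)
    return trace, truth


@pytest.fixture(scope="session")
def noisy_train():
    """10 s train at the 0.5 mV noise level used for robustness checks."""
    gt = APGroundTruth(noise_sd_mV=0.5, seed=11)
    trace, truth = generate_ap_train(gt, duration_s=10.0)
    return trace, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
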