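import os

# single-threaded BLAS: keeps floating-point reduction order, and hence
# every seeded result in this suite, identical across machines
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import logging

import numpy as np
import pytest

import blindmix as bm


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("blindmix").setLevel(logging.WARNING)
    yield


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Noiseless 3-type mixture with 2 decoys; labels are recoverable."""
    return bm.make_scenario(
        m=300, n=12, k_true=3, k_decoy=2,
        ref_noise_sd=0.0, meas_noise_sd=0.0, seed=300,
    )


@pytest.fixture(scope="session")
def noisy_scenario():
    """One instance of the standard noisy benchmark regime."""
    return bm.make_scenario(seed=501)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
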