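import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vepwin as v

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cvep_codes():
    return v.build_cvep_codes()


@pytest.fixture(scope="session")
def ssvep_codes():
    return v.build_ssvep_codes()


@pytest.fixture(scope="session")
def cvep_session(cvep_codes):
    """High-SNR c-VEP training session at the study design (6 blocks x 8
    targets x 3 cycles)."""
    return v.simulate_training_session(
        cvep_codes, n_b=6, cycles_per_trial=3, config=v.SimConfig(snr_db=20.0, seed=7)
    )


@pytest.fixture(scope="session")
def cvep_bank(cvep_session):
    return v.train_bank(cvep_session, M=1)


@pytest.fixture(scope="session")
def ssvep_session(ssvep_codes):
    return v.simulate_training_session(
        ssvep_codes, n_b=6, cycles_per_trial=3, config=v.SimConfig(snr_db=20.0, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
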