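import numpy as np
import pytest

import psmcea


@pytest.fixture(scope="session")
def config():
    return psmcea.base_case_fixture()


@pytest.fixture(scope="session")
def base_results(config):
    return psmcea.run_all(config)


@pytest.fixture(scope="session")
def exp_arm():
    """A moderately censored exponential arm used across reconstruction tests."""
    spec = psmcea.ArmSpec("A", "OS", "exponential", (0.08,), n_subjects=300,
                          cutoff_months=60.0, dropout_rate_per_month=0.01,
                          seed=11)
    return psmcea.simulate_arm(spec)


def km_median(km):
    idx = np.argmax(km.survival <= 0.5)
    return float(km.times[idx])
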