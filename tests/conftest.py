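import numpy as np
import pytest

from dropcycle import ExperimentConfig, RateConstants, integrate


@pytest.fixture(scope="session")
def k_default() -> RateConstants:
    return RateConstants.default()


@pytest.fixture(scope="session")
def cfg25() -> ExperimentConfig:
    """Standard conditions with 25 mM fuel (dynamic-droplet scenario)."""
    return ExperimentConfig(F0=25.0)


@pytest.fixture(scope="session")
def tc25(cfg25, k_default):
    """Integrated 25 mM fuel cycle, shared across read-only tests."""
    return integrate(cfg25, k_default, 90.0)


@pytest.fixture(scope="session")
def recovery_truth() -> RateConstants:
    """Ground-truth constants for parameter-recovery studies: all five
    processes on observable (minutes) timescales."""
    return RateConstants(k0=0.1, k1=0.01, k2=0.6, k3=0.35, k4=0.12)


@pytest.fixture(scope="session")
def hplc_sample_times() -> np.ndarray:
    return np.array([0.25, 0.5, 1, 2, 3, 5, 8, 12, 18, 25, 35, 50])
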