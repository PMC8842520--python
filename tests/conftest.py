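import numpy as np
import pytest

from perifield import StaircaseConfig, WeibullPF, run_running_fit
from perifield.staircase import _m_from_threshold


@pytest.fixture(scope="session")
def default_config() -> StaircaseConfig:
    return StaircaseConfig(initial_threshold=0.3)


@pytest.fixture(scope="session")
def staircase_run(default_config):
    """One complete paired-staircase run against a known observer."""
    observer = WeibullPF(m=0.2)
    rng = np.random.default_rng(42)
    records, threshold = run_running_fit(default_config, observer, rng)
    return observer, records, threshold


def observer_with_threshold(threshold: float, config: StaircaseConfig) -> WeibullPF:
    """Weibull observer whose configured-criterion threshold is `threshold`."""
    m = _m_from_threshold(threshold, config)
    return WeibullPF(m=m, beta=config.beta, gamma=config.gamma, lam=config.lam)
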