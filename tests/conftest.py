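import warnings

import pytest

from cogflux.config import SimulationConfig
from cogflux.simulate import generate_cohort

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def default_cohort():
    """One default 30x42 cohort (no trial stream) shared across tests."""
    return generate_cohort(SimulationConfig(seed=42), include_trials=False)


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort for smoke-level checks."""
    cfg = SimulationConfig(n_participants=8, n_days=21, seed=7)
    return generate_cohort(cfg, include_trials=False)
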