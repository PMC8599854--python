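import pytest

from ithseq.mutational_signatures import load_reference
from ithseq.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-patient cohort with full noise models, reused across tests."""
    cfg = SimulationConfig(n_patients=4, seed=11)
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """No-noise cohort: every observable equals its ground-truth mean."""
    cfg = SimulationConfig(n_patients=3, noise=False, seed=5)
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth
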