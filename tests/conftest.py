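import warnings

import numpy as np
import pytest

from sibewas.synthetic import SimulationConfig, simulate_cohort

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def study_dataset():
    """A mid-sized study with every kind of planted structure, shared across
    test modules (read-only)."""
    cfg = SimulationConfig(
        n_probes=400,
        n_multimodal_probes=3,
        n_bad_samples=5,
        n_xy_probes=10,
        n_crossreactive=8,
        n_snp_overlap=6,
        planted_effects=((0, -3.5), (1, -3.0), (2, 3.0)),
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """No planted effects: methylation independent of CRP."""
    cfg = SimulationConfig(n_probes=150, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
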