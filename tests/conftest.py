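import numpy as np
import pytest

import motorscn as m


@pytest.fixture(scope="session")
def atlas():
    return m.motor_atlas()


@pytest.fixture(scope="session")
def study_cohort():
    """Default synthetic cohort at the study group sizes (27/15/38)."""
    return m.simulate_cohort(m.SimulationSpec(seed=11))


@pytest.fixture(scope="session")
def two_group_cohort():
    """Patient/control pair large enough for stable networks, no extras."""
    spec = m.SimulationSpec(group_sizes={"pPVL": 40, "HC": 50}, seed=7,
                            n_extra_rois=0)
    return m.simulate_cohort(spec)


@pytest.fixture(scope="session")
def hc_network(study_cohort):
    resid = m.residualize(study_cohort, groups=["HC"])
    return m.build_group_network(resid["HC"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
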