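import pytest
from hypothesis import HealthCheck, settings

import littervol as lv

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_design():
    """Cohort matching the emulated study's imaged group sizes (98 pups)."""
    return lv.study_cohort(seed=0)


@pytest.fixture(scope="session")
def study_workspace(study_design):
    return lv.LmeWorkspace(study_design)


@pytest.fixture(scope="session")
def canonical_params():
    """Mid-sized synthetic structure: ~0.8% TBV, litter ICC about 0.2."""
    return lv.StructureParams("canonical", 0.8, 0.84, 0.05, 0.10)
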