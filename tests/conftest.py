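import pytest
from hypothesis import settings

from ipdtplan import BREAST_TUMOR_690NM, PlanConfig, plan_node

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def breast():
    return BREAST_TUMOR_690NM


@pytest.fixture(scope="session")
def default_config():
    return PlanConfig()


@pytest.fixture(scope="session")
def plan_half_cm():
    """Planned 0.5 cm node with default settings (central fiber suffices)."""
    return plan_node(0.5)


@pytest.fixture(scope="session")
def plan_three_cm_four_fibers():
    """3 cm node forced to the four-fiber layout (no escalation)."""
    return plan_node(3.0, n_surrounding=3)
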