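import pytest
from hypothesis import HealthCheck, settings

import retrophylo as rp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return rp.LineagePanel()


@pytest.fixture(scope="session")
def example_matrix():
    return rp.example_matrix()


@pytest.fixture(scope="session")
def example_counts(example_matrix):
    return rp.tabulate(example_matrix)
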