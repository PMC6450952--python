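import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from targetsafe.core_data import build_observations
from targetsafe.synthetic import fixture_small

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_catalogs():
    """The hand-classifiable 5-gene / 6-drug fixture."""
    return fixture_small()


@pytest.fixture(scope="session")
def small_observations(small_catalogs):
    genes, drugs = small_catalogs
    return build_observations(drugs, genes, mode="all")
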