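import pytest

from pvdispro import build_cohorts, default_meddra_map, reference_fixture
from pvdispro.meddra import MRPTSet


@pytest.fixture(scope="session")
def meddra():
    return default_meddra_map()


@pytest.fixture(scope="session")
def mrpts():
    return MRPTSet()


@pytest.fixture(scope="session")
def reference_reports():
    """The deterministic marginal-replication dataset (78,930 reports)."""
    return reference_fixture()


@pytest.fixture(scope="session")
def reference_cohorts(reference_reports):
    return build_cohorts(reference_reports)
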