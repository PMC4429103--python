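import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3() -> nx.Graph:
    return nx.Graph([("A", "B"), ("B", "C")])


@pytest.fixture
def star4() -> nx.Graph:
    return nx.Graph([("H", "A"), ("H", "B"), ("H", "C")])
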