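import pytest

from pipetest import build_graph, discover_suites
from pipetest.execution import ReplayBackend
from pipetest.fixtures import fig3_project


@pytest.fixture(scope="session")
def fig3_root(tmp_path_factory):
    root = tmp_path_factory.mktemp("fig3")
    fig3_project(root)
    return root


@pytest.fixture(scope="session")
def fig3_graph(fig3_root):
    return build_graph(fig3_root)


@pytest.fixture()
def fig3_suites(fig3_root):
    return discover_suites(fig3_root)


@pytest.fixture()
def fig3_backend(fig3_root):
    return ReplayBackend(fig3_root / "tests" / "replay_outputs.yaml",
                         project_root=fig3_root)


# canonical node paths in the fig3 fixture
M1, M2, M3 = "modules/m1.nf", "modules/m2.nf", "modules/m3.nf"
W1, W2, P1 = "workflows/w1.nf", "workflows/w2.nf", "p1.nf"
SUITE = {
    "M1": "tests/m1.test.yaml", "M2": "tests/m2.test.yaml",
    "M3": "tests/m3.test.yaml", "W2": "tests/w2.test.yaml",
    "P1": "tests/p1.test.yaml",
}
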