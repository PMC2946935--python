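import pytest

from deskpipe import fixtures as fx


@pytest.fixture
def toy_tools(tmp_path):
    return fx.write_toy_tools(str(tmp_path / "tools"))


@pytest.fixture
def chain_workflow(tmp_path):
    """Parsed toy chain workflow (A -> B) plus its directory."""
    from deskpipe.workflow_model import parse_workflow_file

    path = fx.make_toy_workflow("chain", str(tmp_path / "chain"))
    return parse_workflow_file(path), tmp_path / "chain"


@pytest.fixture
def diamond_workflow(tmp_path):
    from deskpipe.workflow_model import parse_workflow_file

    path = fx.make_toy_workflow("diamond", str(tmp_path / "diamond"))
    return parse_workflow_file(path), tmp_path / "diamond"


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down fixture configuration for fast engine-level tests."""
    return fx.FixtureConfig(seed=7, n_labels=4, volume_shape=(48, 48, 48),
                            cohort_sizes={"AD": 3, "MCI": 4, "NC": 5})
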