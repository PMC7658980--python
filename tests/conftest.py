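import pytest

from ballastflow.flow_networks import build_trajectories
from ballastflow.synthetic import worked_example_fixture, worked_example_ports


@pytest.fixture(scope="session")
def worked_movements():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def worked_trajectories(worked_movements):
    return build_trajectories(worked_movements)


@pytest.fixture(scope="session")
def worked_ports():
    return worked_example_ports()
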