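import pytest

from rrest.config import EngineConfig, PatientProfile, default_config
from rrest.flow import default_flow_graph
from rrest.simulator import AgentPolicy, ScenarioSpec, run_scenario


@pytest.fixture(scope="session")
def graph():
    return default_flow_graph()


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def profile():
    return PatientProfile(weight_kg=10.0)


@pytest.fixture(scope="session")
def ideal_log():
    """Error-free guided team on the default asystole scenario."""
    return run_scenario(ScenarioSpec(), AgentPolicy.ideal("intervention"))


@pytest.fixture(scope="session")
def ideal_control_log():
    return run_scenario(ScenarioSpec(), AgentPolicy.ideal("control"))
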