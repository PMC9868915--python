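import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from instmfa.network import FluxState, parse_model
from instmfa.synthetic import (default_design, flux_model_for,
                               generate_experiment)

TIMES = np.array([0, 0.5, 1, 2, 4, 8, 10, 15, 20, 30, 60, 120, 270.0])


@pytest.fixture(scope="session")
def mini_design():
    return default_design()


@pytest.fixture(scope="session")
def mini_experiment(mini_design):
    df, record = generate_experiment(mini_design, seed=20231)
    return df, record


@pytest.fixture(scope="session")
def mini_problem(mini_design, mini_experiment):
    df, record = mini_experiment
    return flux_model_for(mini_design, df, record)


@pytest.fixture(scope="session")
def mini_fit(mini_design, mini_problem):
    # warm start from truth plus two random restarts keeps the suite fast;
    # the full multistart path is exercised in the acceptance tests
    start = mini_problem.state_to_theta(mini_design.truth, mini_design.mixing)
    return mini_problem.fit(n_starts=2, seed=7, start=start)


@pytest.fixture()
def washout_model():
    """One balanced pool fed by a partially labelled substrate."""
    return parse_model("""
pool S 1 source
pool A 1
pool OUT 1 sink
rxn inflow: S (a) -> A (a)
rxn outflow: A (a) -> OUT (a)
fix inflow 1.0
substrate S 0.4 0.6
measure A: A
""")


@pytest.fixture()
def washout_state():
    return FluxState({"inflow": 1.0, "outflow": 1.0}, {}, {"A": 2.0})


@pytest.fixture()
def condensation_model():
    return parse_model("""
pool SA 1 source
pool SB 1 source
pool A 1
pool B 1
pool C 2
pool OUT 2 sink
rxn ra: SA (a) -> A (a)
rxn rb: SB (a) -> B (a)
rxn rc: A (a) + B (b) -> C (ab)
rxn ro: C (ab) -> OUT (ab)
fix ra 1.0
substrate SA 0.5 0.5
substrate SB 0.5 0.5
measure C: C
""")


@pytest.fixture()
def scrambling_model():
    """Condensation through a rotationally symmetric intermediate."""
    return parse_model("""
pool SA 1 source
pool SB 1 source
pool A 1
pool B 1
pool S 2 symmetric
pool C 2
pool OUT 2 sink
rxn ra: SA (a) -> A (a)
rxn rb: SB (a) -> B (a)
rxn rc: A (a) + B (b) -> S (ab)
rxn rd: S (ab) -> C (ab)
rxn ro: C (ab) -> OUT (ab)
fix ra 1.0
substrate SA 0.1 0.9
substrate SB 0.7 0.3
measure C: C
""")
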