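import numpy as np
import pytest
from hypothesis import settings

import boolteams as bt
from boolteams.synthetic import SyntheticSpec

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toggle():
    """Plain two-node mutual-inhibition switch."""
    return bt.make_toggle_switch()


@pytest.fixture(scope="session")
def toggle_self():
    """Toggle switch with self-activations (tie-rule showcase)."""
    return bt.make_toggle_switch(self_activation=True)


@pytest.fixture(scope="session")
def chain():
    """Signal -> core -> output chain: SIG -> A -> B."""
    adj = np.zeros((3, 3), dtype=np.int8)
    adj[0, 1] = 1
    adj[1, 2] = 1
    return bt.RegulatoryNetwork(["SIG", "A", "B"], adj)


@pytest.fixture(scope="session")
def four_node_two_team():
    """Two 2-node teams: full within-team activation, full cross inhibition."""
    spec = SyntheticSpec(
        n_team1=2, n_team2=2, p_within=1.0, p_cross=1.0,
        n_signal=0, n_output=0, seed=0,
    )
    return bt.make_team_network(spec)


@pytest.fixture(scope="session")
def emp_net():
    """Deterministic 22-node EMP-like synthetic network (strong teams)."""
    return bt.emp_like_network(seed=0)


@pytest.fixture(scope="session")
def emp_partition(emp_net):
    infl = bt.influence_matrix(emp_net)
    return bt.assign_team_identity(
        bt.detect_teams(infl, emp_net.core), emp_net.node_names
    )
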