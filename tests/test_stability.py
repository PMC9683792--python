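import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import boolteams as bt
from boolteams.influence import TeamPartition
from boolteams.stability import BIMODALITY_THRESHOLD


class TestFrustration:
    def test_toggle_terminal_state_unfrustrated(self, toggle):
        assert bt.frustration(toggle, [1, -1]) == 0.0

    def test_toggle_symmetric_state_fully_frustrated(self, toggle):
        assert bt.frustration(toggle, [1, 1]) == 1.0

    @given(st.lists(st.sampled_from([-1, 1]), min_size=22, max_size=22))
    def test_global_sign_flip_symmetry(self, state):
        net = bt.emp_like_network(seed=0)
        s = np.array(state, dtype=np.int8)
        assert bt.frustration(net, s) == pytest.approx(bt.frustration(net, -s))

    def test_bounded_in_unit_interval(self, emp_net):
        rng = np.random.default_rng(1)
        for _ in range(20):
            s = rng.choice([-1, 1], size=emp_net.n_nodes)
            assert 0.0 <= bt.frustration(emp_net, s) <= 1.0

    def test_edgeless_network_rejected(self):
        with pytest.warns(UserWarning):
            net = bt.RegulatoryNetwork(["A", "B"], np.zeros((2, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            bt.frustration(net, [1, 1])

    def test_terminal_states_less_frustrated_than_hybrids(self, emp_net, emp_partition):
        ens = bt.sample_steady_states(emp_net, n_init=20_000, seed=4)
        fr = {"terminal": [], "hybrid": []}
        for s in ens.states:
            lab = bt.classify_phenotype(s, emp_partition).label
            fr["hybrid" if lab == "hybrid" else "terminal"].append(
                bt.frustration(emp_net, s)
            )
        assert max(fr["terminal"]) < min(fr["hybrid"])


class TestPerturbState:
    def test_single_flip(self):
        assert tuple(bt.perturb_state([1, -1], [0])) == (-1, -1)

    def test_double_flip_is_identity(self):
        s = np.array([1, -1, 1], dtype=np.int8)
        assert np.array_equal(bt.perturb_state(bt.perturb_state(s, [0, 2]), [0, 2]), s)

    def test_empty_set_warns_and_keeps_state(self):
        with pytest.warns(UserWarning):
            out = bt.perturb_state([1, -1], [])
        assert tuple(out) == (1, -1)


class TestCoherence:
    def test_output_node_always_restored(self, chain):
        # state: SIG on, A on, B on is a fixed point; B regulates nothing
        assert bt.single_node_coherence(chain, [1, 1, 1], 2, K=50, seed=0) == 1.0

    def test_signal_node_never_restored(self, chain):
        assert bt.single_node_coherence(chain, [1, 1, 1], 0, K=50, seed=0) == 0.0

    def test_toggle_half_coherent(self, toggle):
        # first update decides: updating the flipped node restores, the other locks
        val = bt.single_node_coherence(toggle, [1, -1], 0, K=800, seed=1)
        assert abs(val - 0.5) < 0.07

    def test_requires_fixed_point(self, toggle):
        with pytest.raises(ValueError):
            bt.single_node_coherence(toggle, [1, 1], 0)

    def test_profile_mean_is_mean_of_per_node(self, toggle):
        prof = bt.coherence(toggle, [1, -1], K=40, seed=2)
        assert prof.mean_coherence == pytest.approx(prof.per_node.mean())
        assert prof.per_node.shape == (2,)

    def test_flip_landing_on_another_attractor_gives_zero(self):
        # single self-activating node pair: both states of each node are fixed
        adj = np.zeros((2, 2), dtype=np.int8)
        adj[0, 0] = adj[1, 1] = 1
        net = bt.RegulatoryNetwork(["A", "B"], adj)
        prof = bt.coherence(net, [1, 1], K=20, seed=0)
        assert prof.mean_coherence == 0.0

    def test_terminal_core_flip_coherence_is_one(self, emp_net, emp_partition):
        ens = bt.sample_steady_states(emp_net, n_init=10_000, seed=5)
        idx = int(np.argmax(ens.ssf))
        state = ens.states[idx]
        assert bt.classify_phenotype(state, emp_partition).label in ("E", "M")
        for node in emp_net.core[:5]:
            assert bt.single_node_coherence(emp_net, state, int(node), K=25, seed=6) == 1.0

    def test_core_coherence_chain_follows_signal(self, chain):
        assert bt.core_coherence_on_signal_perturbation(chain, [1, 1, 1], K=30, seed=0) == 0.0

    def test_core_coherence_one_for_terminal_emp_state(self, emp_net, emp_partition):
        ens = bt.sample_steady_states(emp_net, n_init=10_000, seed=7)
        state = ens.states[int(np.argmax(ens.ssf))]
        val = bt.core_coherence_on_signal_perturbation(emp_net, state, K=25, seed=8)
        assert val == 1.0

    def test_core_coherence_needs_signals(self, toggle):
        with pytest.raises(ValueError):
            bt.core_coherence_on_signal_perturbation(toggle, [1, -1])


class TestPhenotype:
    @pytest.fixture()
    def partition(self):
        part = TeamPartition(np.array([0, 1]), np.array([2, 3]), np.zeros((2, 2)), 0.5)
        part.identity = {"team1": "epithelial", "team2": "mesenchymal"}
        return part

    def test_pure_epithelial(self, partition):
        ph = bt.classify_phenotype([1, 1, -1, -1], partition)
        assert ph.label == "E" and ph.emt_score == -1.0

    def test_pure_mesenchymal(self, partition):
        ph = bt.classify_phenotype([-1, -1, 1, 1], partition)
        assert ph.label == "M" and ph.emt_score == 1.0

    def test_mixed_active_is_hybrid(self, partition):
        assert bt.classify_phenotype([1, -1, 1, -1], partition).label == "hybrid"
        assert bt.classify_phenotype([1, -1, 1, -1], partition).emt_score == 0.0

    def test_all_inactive_core_is_hybrid(self, partition):
        assert bt.classify_phenotype([-1, -1, -1, -1], partition).label == "hybrid"

    def test_generic_teams_use_generic_labels(self):
        part = TeamPartition(np.array([0]), np.array([1]), np.zeros((2, 2)), 0.5)
        assert bt.classify_phenotype([1, -1], part).label == "team1"


class TestBimodalityCoefficient:
    def test_uniform_limit(self):
        rng = np.random.default_rng(0)
        bc = bt.bimodality_coefficient(rng.uniform(size=100_000))
        assert bc == pytest.approx(5 / 9, abs=0.01)

    def test_normal_limit(self):
        rng = np.random.default_rng(1)
        bc = bt.bimodality_coefficient(rng.normal(size=100_000))
        assert bc == pytest.approx(1 / 3, abs=0.01)

    def test_two_point_sample_flags_bimodal(self):
        x = np.array([0.0, 1.0] * 500)
        assert bt.bimodality_coefficient(x) > BIMODALITY_THRESHOLD
        assert bt.bimodality_coefficient(x) == pytest.approx(1.0, abs=0.01)

    def test_small_or_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            bt.bimodality_coefficient([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            bt.bimodality_coefficient([2.0] * 10)


def test_coherence_ssf_frustration_correlations_on_strong_teams(emp_net, emp_partition):
    """Across fixed points of a strong-team network: coherence tracks SSF
    positively, frustration negatively (the bimodal-landscape signature)."""
    from scipy.stats import spearmanr

    ens = bt.sample_steady_states(emp_net, n_init=20_000, seed=9)
    rng = np.random.default_rng(10)
    coh = np.array(
        [bt.coherence(emp_net, s, K=15, seed=rng).mean_coherence for s in ens.states]
    )
    fr = np.array([bt.frustration(emp_net, s) for s in ens.states])
    assert spearmanr(coh, ens.ssf).statistic > 0
    assert spearmanr(fr, ens.ssf).statistic < 0
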