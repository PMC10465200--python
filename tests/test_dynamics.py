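import numpy as np
import pytest

import trophica as tr

from conftest import cycle_network, path_network


class TestLowestLevelNodes:
    def test_path_bottom_half(self):
        lv = tr.trophic_levels(path_network(4))
        assert list(tr.lowest_level_nodes(lv, 0.5)) == [0, 1]

    def test_ties_break_by_index(self):
        lv = tr.TrophicLevels(h=np.zeros(4), pinned_node=0)
        assert list(tr.lowest_level_nodes(lv, 0.25)) == [0]

    def test_five_percent_of_500(self):
        lv = tr.TrophicLevels(h=np.arange(500, dtype=float), pinned_node=0)
        assert len(tr.lowest_level_nodes(lv, 0.05)) == 25

    def test_fraction_out_of_range_errors(self):
        lv = tr.TrophicLevels(h=np.zeros(10), pinned_node=0)
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                tr.lowest_level_nodes(lv, bad)


def _naive_majority(net, s, n_steps):
    """Reference implementation: no early exit, explicit loops."""
    s = s.copy()
    for _ in range(n_steps):
        nxt = s.copy()
        for i in range(net.n_nodes):
            tot = sum(s[j] for j, k in net.edges if k == i)
            if tot > 0:
                nxt[i] = 1
            elif tot < 0:
                nxt[i] = -1
        s = nxt
    return s


class TestMajorityVote:
    def test_influence_propagates_down_a_path(self):
        res = tr.majority_vote_run(path_network(3), np.array([-1, 1, 1]), 2)
        assert np.all(res.final_state == -1)

    def test_consensus_is_absorbing(self):
        net = cycle_network(5)
        res = tr.majority_vote_run(net, np.ones(5, dtype=int), 50)
        assert np.all(res.final_state == 1) and res.mean_state == 1.0

    def test_states_stay_spins(self):
        rng = np.random.default_rng(0)
        net, _ = tr.generate_network(tr.GeneratorConfig(30, 3.0, 1.0, seed=0))
        s = rng.choice([-1, 1], size=30)
        res = tr.majority_vote_run(net, s, 17)
        assert set(np.unique(res.final_state)) <= {-1, 1}

    def test_matches_naive_reference(self):
        """Early-exit bookkeeping agrees with a plain fixed-step loop."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(3, 10))
            pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
            idx = rng.choice(len(pairs), size=int(rng.integers(1, len(pairs))), replace=False)
            net = tr.DirectedNetwork(n, [pairs[k] for k in idx])
            s = rng.choice([-1, 1], size=n)
            for n_steps in (1, 2, 7, 8):
                fast = tr.majority_vote_run(net, s, n_steps).final_state
                assert np.array_equal(fast, _naive_majority(net, s, n_steps))

    def test_invalid_state_errors(self):
        with pytest.raises(ValueError):
            tr.majority_vote_run(path_network(3), np.array([0, 1, 1]), 1)


class TestVoter:
    def test_single_edge_copies_source(self):
        net = tr.DirectedNetwork(2, [(0, 1)])
        res = tr.voter_run(net, np.array([-1, 1]), 1, seed=0)
        assert np.array_equal(res.final_state, [-1, -1])

    def test_consensus_is_absorbing(self):
        net = cycle_network(6)
        res = tr.voter_run(net, -np.ones(6, dtype=int), 100, seed=1)
        assert np.all(res.final_state == -1)

    def test_seed_reproducibility(self):
        net, _ = tr.generate_network(tr.GeneratorConfig(40, 3.0, 1.0, seed=2))
        s = tr.spin_state(40, range(8))
        a = tr.voter_run(net, s, 200, seed=9).final_state
        b = tr.voter_run(net, s, 200, seed=9).final_state
        assert np.array_equal(a, b)

    def test_nodes_without_in_neighbours_keep_state(self):
        net = tr.DirectedNetwork(3, [(0, 1), (0, 2)])  # node 0 has no inputs
        res = tr.voter_run(net, np.array([-1, 1, 1]), 10, seed=0)
        assert res.final_state[0] == -1

    def test_async_mode_runs_and_stays_spins(self):
        net, _ = tr.generate_network(tr.GeneratorConfig(30, 3.0, 1.0, seed=3))
        s = tr.spin_state(30, range(6))
        res = tr.voter_run(net, s, 20, seed=4, mode="async")
        assert set(np.unique(res.final_state)) <= {-1, 1}


class TestKuramoto:
    def test_order_parameter_limits(self):
        n = 1000
        uniform = np.linspace(0, 2 * np.pi, n, endpoint=False)
        assert tr.phase_order_parameter(uniform) == pytest.approx(0.0, abs=1e-10)
        assert tr.phase_order_parameter(np.full(n, 1.3)) == pytest.approx(1.0)

    def test_identical_oscillators_stay_in_phase(self):
        net, _ = tr.generate_network(tr.GeneratorConfig(40, 4.0, 1.0, seed=6))
        cfg = tr.KuramotoConfig(coupling=10.0, omegas=np.ones(40), t_end=10.0)
        res = tr.kuramoto_run(net, cfg)
        assert res.order_parameter == pytest.approx(1.0, abs=1e-4)
        assert res.mean_state == pytest.approx(1.0, abs=1e-4)
        assert res.frequency_std < 1e-4

    def test_basal_nodes_follow_natural_frequency(self):
        net = tr.DirectedNetwork(3, [(0, 1), (0, 2)])
        cfg = tr.KuramotoConfig(coupling=5.0, omegas=np.array([2.0, 1.0, 1.0]), t_end=10.0)
        res = tr.kuramoto_run(net, cfg)
        assert res.final_state[0] == pytest.approx(2.0, abs=1e-3)

    def test_frequency_sync_at_strong_coupling(self):
        """Across-node frequency spread stays below 1 at K = 20<k>."""
        net, levels = tr.generate_network(tr.GeneratorConfig(100, 5.0, 1.0, seed=7))
        low = tr.lowest_level_nodes(levels, 0.2)
        omegas = np.ones(100)
        omegas[low] = -1.0
        res = tr.kuramoto_run(net, tr.KuramotoConfig(coupling=100.0, omegas=omegas))
        assert res.frequency_std < 1.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            tr.KuramotoConfig(coupling=-1.0, omegas=np.ones(3))
        with pytest.raises(ValueError):
            tr.KuramotoConfig(coupling=1.0, omegas=np.ones(3), t_end=0.0)


class TestInfluenceTransition:
    def test_scaled_down_transition_majority_and_voter(self, influence_ensemble):
        """Coherent networks flip to the perturbed minority; incoherent resist."""
        for dyn in ("majority", "voter"):
            medians = {}
            for t_gen, nets in influence_ensemble.items():
                outs = []
                for k, (net, levels) in enumerate(nets):
                    low = tr.lowest_level_nodes(levels, 0.2)
                    s0 = tr.spin_state(net.n_nodes, low)
                    if dyn == "majority":
                        res = tr.majority_vote_run(net, s0, 1000)
                    else:
                        res = tr.voter_run(net, s0, 1000, seed=k)
                    outs.append(res.mean_state)
                medians[t_gen] = np.median(outs)
            assert medians[0.02] <= -0.5, dyn
            assert medians[100.0] >= 0.5, dyn
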