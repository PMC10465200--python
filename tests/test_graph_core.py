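import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trophica as tr
from trophica.graph_core import out_component_sizes

from conftest import cycle_network, path_network


class TestDirectedNetwork:
    def test_rejects_self_loops_and_bad_indices(self):
        with pytest.raises(ValueError, match="self-loop"):
            tr.DirectedNetwork(2, [(0, 0)])
        with pytest.raises(ValueError, match="outside"):
            tr.DirectedNetwork(2, [(0, 2)])

    def test_adjacency_orientation(self):
        net = tr.DirectedNetwork(3, [(0, 1), (1, 2)])
        a = net.adjacency.toarray()
        assert a[0, 1] == 1 and a[1, 0] == 0  # A_ij = 1 iff edge i -> j

    def test_duplicate_edges_collapse(self):
        net = tr.DirectedNetwork(2, [(0, 1), (0, 1)])
        assert net.n_edges == 1


class TestEdgeListIO:
    @pytest.mark.parametrize(
        "text,n_nodes,edges",
        [
            ("a b\nb c\n", 3, {(0, 1), (1, 2)}),
            ("a b\na b\n", 2, {(0, 1)}),  # duplicate collapsed
            ("a a\na b\n", 2, {(0, 1)}),  # self-loop dropped
        ],
    )
    def test_parse(self, tmp_path, text, n_nodes, edges):
        p = tmp_path / "net.tsv"
        p.write_text(text)
        net = tr.read_edge_list(p)
        assert net.n_nodes == n_nodes
        assert net.edges == frozenset(edges)

    def test_parse_warnings_logged(self, tmp_path, caplog):
        p = tmp_path / "net.tsv"
        p.write_text("a b\na b\nc c\n")
        with caplog.at_level("WARNING"):
            tr.read_edge_list(p)
        assert "duplicate" in caplog.text and "self-loop" in caplog.text

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a b\nq r s\n")
        with pytest.raises(ValueError, match="line 2"):
            tr.read_edge_list(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("# only a comment\n")
        with pytest.raises(ValueError, match="empty"):
            tr.read_edge_list(p)

    def test_roundtrip_preserves_edges(self, tmp_path):
        net = tr.DirectedNetwork(4, [(0, 1), (2, 1), (3, 0)], node_labels="wxyz")
        p = tmp_path / "out.tsv"
        tr.write_edge_list(net, p)
        again = tr.read_edge_list(p)
        # labels map back to the same edge set under the label bijection
        relabel = {again.node_labels[k]: k for k in range(again.n_nodes)}
        orig = {(relabel[net.node_labels[i]], relabel[net.node_labels[j]]) for i, j in net.edges}
        assert again.edges == frozenset(orig)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(edges=st.sets(st.tuples(st.integers(0, 7), st.integers(0, 7)).filter(lambda e: e[0] != e[1]), min_size=1, max_size=12))
    def test_roundtrip_random_graphs(self, tmp_path_factory, edges):
        nodes = sorted({u for e in edges for u in e})
        remap = {u: k for k, u in enumerate(nodes)}
        net = tr.DirectedNetwork(len(nodes), [(remap[i], remap[j]) for i, j in edges])
        p = tmp_path_factory.mktemp("rt") / "g.tsv"
        tr.write_edge_list(net, p)
        assert tr.read_edge_list(p).n_edges == net.n_edges

    def test_graphml_roundtrip(self, tmp_path):
        net = tr.DirectedNetwork(3, [(0, 1), (1, 2)], node_labels=["a", "b", "c"])
        p = tmp_path / "g.graphml"
        tr.write_graphml(net, p)
        again = tr.read_graphml(p)
        assert again.n_nodes == 3 and again.n_edges == 2


class TestDegrees:
    @pytest.mark.parametrize(
        "net,in_deg,out_deg",
        [
            (path_network(3), (0, 1, 1), (1, 1, 0)),
            (cycle_network(3), (1, 1, 1), (1, 1, 1)),
            (tr.DirectedNetwork(3, [(0, 1), (0, 2), (1, 2)]), (0, 1, 2), (2, 1, 0)),
        ],
    )
    def test_examples(self, net, in_deg, out_deg):
        i, o = tr.degrees(net)
        assert tuple(i) == in_deg and tuple(o) == out_deg
        assert i.sum() == o.sum() == net.n_edges


def _bfs_out_sizes(net):
    """Reference: plain BFS from every node."""
    adj = {i: [] for i in range(net.n_nodes)}
    for i, j in net.edges:
        adj[i].append(j)
    sizes = []
    for s in range(net.n_nodes):
        seen, stack = {s}, [s]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        sizes.append(len(seen) - 1)
    return np.array(sizes)


class TestOutComponents:
    @pytest.mark.parametrize(
        "net,sizes",
        [
            (path_network(3), (2, 1, 0)),
            (cycle_network(3), (2, 2, 2)),
            (tr.DirectedNetwork(3, [(0, 1), (0, 2)]), (2, 0, 0)),
        ],
    )
    def test_examples(self, net, sizes):
        assert tuple(out_component_sizes(net)) == sizes

    def test_exhaustive_small_graphs_match_bfs(self):
        """Every 4-node digraph with up to 3 edges, enumerated exhaustively."""
        pairs = [(i, j) for i in range(4) for j in range(4) if i != j]
        for m in range(0, 4):
            for combo in itertools.combinations(pairs, m):
                net = tr.DirectedNetwork(4, combo)
                assert np.array_equal(out_component_sizes(net), _bfs_out_sizes(net))

    def test_random_graphs_match_bfs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
            m = int(rng.integers(0, min(7, len(pairs) + 1)))
            idx = rng.choice(len(pairs), size=m, replace=False)
            net = tr.DirectedNetwork(n, [pairs[k] for k in idx])
            assert np.array_equal(out_component_sizes(net), _bfs_out_sizes(net))

    def test_strongly_connected_gives_n_minus_one(self):
        net = cycle_network(10)
        assert np.all(out_component_sizes(net) == 9)


class TestComponents:
    def test_cycle_single_strong_component(self):
        assert tr.strongly_connected_components(cycle_network(3)) == [{0, 1, 2}]

    def test_path_singleton_strong_one_weak(self):
        net = path_network(3)
        assert sorted(tr.strongly_connected_components(net), key=min) == [{0}, {1}, {2}]
        assert tr.weakly_connected_components(net) == [{0, 1, 2}]

    def test_two_disjoint_two_cycles(self):
        net = tr.DirectedNetwork(4, [(0, 1), (1, 0), (2, 3), (3, 2)])
        assert sorted(tr.strongly_connected_components(net), key=min) == [{0, 1}, {2, 3}]

    def test_strong_refines_weak(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
            idx = rng.choice(len(pairs), size=int(rng.integers(1, len(pairs))), replace=False)
            net = tr.DirectedNetwork(n, [pairs[k] for k in idx])
            weak = tr.weakly_connected_components(net)
            for strong in tr.strongly_connected_components(net):
                assert any(strong <= w for w in weak)
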