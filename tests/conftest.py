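import numpy as np
import pytest

import trophica as tr


def path_network(n: int) -> tr.DirectedNetwork:
    return tr.DirectedNetwork(n, [(i, i + 1) for i in range(n - 1)])


def cycle_network(n: int) -> tr.DirectedNetwork:
    return tr.DirectedNetwork(n, [(i, (i + 1) % n) for i in range(n)])


def random_connected_digraph(rng: np.random.Generator, n_max: int = 5) -> tr.DirectedNetwork:
    """A weakly connected simple digraph on 2..n_max nodes."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
        m = int(rng.integers(n - 1, len(pairs) + 1))
        idx = rng.choice(len(pairs), size=m, replace=False)
        net = tr.DirectedNetwork(n, [pairs[k] for k in idx])
        if len(tr.weakly_connected_components(net)) == 1:
            return net


@pytest.fixture(scope="session")
def influence_ensemble():
    """Generated networks at the two temperature extremes used by the
    influence-transition checks: N=100, <k>=5, no basal nodes, 10 seeds."""
    ensemble = {}
    for t_gen in (0.02, 100.0):
        nets = []
        for seed in range(10):
            cfg = tr.GeneratorConfig(
                n_nodes=100, mean_degree=5.0, t_gen=t_gen, seed=seed
            )
            nets.append(tr.generate_network(cfg))
        ensemble[t_gen] = nets
    return ensemble
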