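"""Synthetic directed networks with tunable trophic incoherence.

The generator adapts the generalized preferential preying model to the
basal-node-free trophic level definition.  It proceeds in two stages:

1. *Seed graph*: every non-basal node receives exactly one incoming edge whose
   source is drawn uniformly from the other nodes; designated basal nodes
   receive no in-edges (they keep in-degree zero throughout).
2. *Growth*: the trophic levels ``h~`` of the seed graph are computed once and
   frozen.  Candidate ordered pairs ``(i, j)`` (absent, non-loop, ``j`` not
   basal) are then added until the target edge count ``round(N * <k>)`` is
   reached, each accepted with the Gaussian preference

       P_ij = exp(-(h~_j - h~_i - 1)^2 / (2 * T_gen)).

Low temperatures ``T_gen`` place edges only across level steps close to one
(coherent, hierarchical networks, F -> 0); high temperatures accept anything
(incoherent networks, F -> 1).  The realized incoherence tracks the analytic
approximation ``F ~ T_gen / (1 + T_gen)``.

Two sampling schemes draw from the same edge distribution: ``"exact"``
(default) ranks candidates by Gumbel-perturbed log-weights, which is
equivalent to sequential sampling without replacement proportional to
``P_ij`` and never stalls even when every remaining weight underflows;
``"rejection"`` reproduces the textbook accept/reject loop and raises once
``max_attempts`` proposals are exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import DirectedNetwork
from .trophic import TrophicLevels, trophic_levels

__all__ = ["GeneratorConfig", "initial_configuration", "generate_network"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Recipe for one synthetic network.

    Parameters
    ----------
    n_nodes:
        Number of nodes ``N``.
    mean_degree:
        Target mean degree ``<k>``; the final edge count is
        ``round(N * <k>)`` including the seed edges.
    t_gen:
        Generation temperature (positive) controlling incoherence.
    n_basal:
        Number of nodes (indices ``0 .. n_basal-1``) kept at in-degree zero.
    seed:
        RNG seed; equal configs with equal seeds give identical networks.
    max_attempts:
        Proposal cap for the rejection sampler.
    """

    n_nodes: int
    mean_degree: float
    t_gen: float
    n_basal: int = 0
    seed: int | None = None
    max_attempts: int = 2_000_000

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if self.mean_degree <= 0:
            raise ValueError("mean_degree must be positive")
        if self.t_gen <= 0:
            raise ValueError("t_gen must be positive")
        if not 0 <= self.n_basal < self.n_nodes:
            raise ValueError("n_basal must satisfy 0 <= n_basal < n_nodes")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be positive")
        if self.n_edges_target < self.n_nodes - self.n_basal:
            raise ValueError(
                "target edge count round(n_nodes * mean_degree) must cover the "
                f"{self.n_nodes - self.n_basal} seed edges"
            )
        capacity = (self.n_nodes - 1) * (self.n_nodes - self.n_basal)
        if self.n_edges_target > capacity:
            raise ValueError(
                f"target edge count {self.n_edges_target} exceeds the "
                f"{capacity} ordered pairs available"
            )

    @property
    def n_edges_target(self) -> int:
        return int(round(self.n_nodes * self.mean_degree))


def initial_configuration(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> DirectedNetwork:
    """Seed graph: in-degree one everywhere except the basal nodes."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, nb = config.n_nodes, config.n_basal
    targets = np.arange(nb, n)
    sources = rng.integers(0, n - 1, size=len(targets))
    sources[sources >= targets] += 1  # skip self as a source
    return DirectedNetwork(n, list(zip(sources.tolist(), targets.tolist())))


def _candidate_pairs(config: GeneratorConfig, existing: frozenset) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_nodes
    open_ = np.ones((n, n), dtype=bool)
    np.fill_diagonal(open_, False)
    if config.n_basal:
        open_[:, : config.n_basal] = False
    if existing:
        e = np.array(sorted(existing), dtype=np.int64)
        open_[e[:, 0], e[:, 1]] = False
    return np.nonzero(open_)


def generate_network(
    config: GeneratorConfig, method: str = "exact"
) -> tuple[DirectedNetwork, TrophicLevels]:
    """Generate one network and the trophic levels of the *final* graph.

    The seed-graph levels ``h~`` are computed once and never updated during
    growth; the returned :class:`~trophica.trophic.TrophicLevels` are
    recomputed on the finished network.

    Raises
    ------
    ValueError
        If the rejection sampler exceeds ``max_attempts`` (suggesting a higher
        ``t_gen`` or lower density), or the config is infeasible.
    """
    if method not in ("exact", "rejection"):
        raise ValueError("method must be 'exact' or 'rejection'")
    rng = np.random.default_rng(config.seed)
    seed_net = initial_configuration(config, rng)
    h0 = trophic_levels(seed_net, on_edgeless="zero").h
    m_extra = config.n_edges_target - seed_net.n_edges
    if m_extra == 0:
        return seed_net, trophic_levels(seed_net, on_edgeless="zero")
    ii, jj = _candidate_pairs(config, seed_net.edges)
    if len(ii) < m_extra:
        raise ValueError("candidate pool smaller than the number of edges needed")
    logw = -((h0[jj] - h0[ii] - 1.0) ** 2) / (2.0 * config.t_gen)
    if method == "exact":
        # Gumbel-top-k == sampling without replacement proportional to exp(logw)
        keys = logw + rng.gumbel(size=len(logw))
        chosen = np.argpartition(keys, -m_extra)[-m_extra:]
    else:
        chosen = _rejection_sample(rng, np.exp(logw), m_extra, config.max_attempts)
    new_edges = set(seed_net.edges)
    new_edges.update(zip(ii[chosen].tolist(), jj[chosen].tolist()))
    net = DirectedNetwork(config.n_nodes, new_edges)
    assert net.n_edges == config.n_edges_target
    return net, trophic_levels(net, on_edgeless="zero")


def _rejection_sample(
    rng: np.random.Generator, p: np.ndarray, m: int, max_attempts: int
) -> np.ndarray:
    """Draw ``m`` distinct indices by uniform proposal + accept with prob ``p``.

    Proposals are generated in vectorized batches but consumed strictly in
    order, so the process is identical to one-at-a-time rejection sampling.
    """
    taken = np.zeros(len(p), dtype=bool)
    chosen: list[int] = []
    attempts = 0
    batch = 8192
    while len(chosen) < m:
        if attempts >= max_attempts:
            raise ValueError(
                f"rejection sampling exhausted max_attempts={max_attempts} with "
                f"{len(chosen)}/{m} edges placed; consider a higher t_gen, a "
                "lower density, or method='exact'"
            )
        size = min(batch, max_attempts - attempts)
        idx = rng.integers(0, len(p), size=size)
        acc = rng.random(size=size) < p[idx]
        attempts += size
        for k in idx[acc]:
            if not taken[k]:
                taken[k] = True
                chosen.append(int(k))
                if len(chosen) == m:
                    break
    return np.array(chosen, dtype=np.int64)
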