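"""Generalized rock-paper-scissors games on a strategy network.

Strategies are the nodes of a directed "strategy network"; an edge ``i -> j``
means strategy ``i`` dominates strategy ``j`` (edge *sources* win, so that
successful strategies sit at low trophic level; a config flag flips the
convention).  A well-mixed population of players, each holding one strategy,
meets in random pairwise encounters: the player holding the losing strategy
adopts the winning one, reciprocal dominance is resolved by a fair coin, and
unrelated strategies leave both players unchanged.  The long-run success of a
strategy is its time-and-player-averaged occupancy — the probability of being
played per player per encounter.

The module also provides the centrality rankings (trophic level, reversed
PageRank, out-degree, degree imbalance) used to ask which ranking best
predicts strategy success, via cumulative play-probability curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import DirectedNetwork, degrees
from .trophic import TrophicLevels

__all__ = [
    "GameConfig",
    "PlayRecord",
    "play_game",
    "pagerank",
    "centrality_rankings",
    "cumulative_play_curve",
    "curve_area",
]


@dataclass(frozen=True)
class GameConfig:
    """Population size, encounter budget and RNG seed for one game."""

    n_players: int = 1000
    n_encounters: int = 100_000
    seed: int | None = None
    source_wins: bool = True

    def __post_init__(self):
        if self.n_players < 2:
            raise ValueError("n_players must be at least 2")
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be positive")


@dataclass(frozen=True)
class PlayRecord:
    """Per-strategy play probability (non-negative, sums to 1)."""

    play_probability: np.ndarray


def play_game(strategy_net: DirectedNetwork, config: GameConfig) -> PlayRecord:
    """Simulate the population game and return average strategy occupancies.

    Players start with independent uniform strategies; each encounter pairs
    two distinct players uniformly at random.  Occupancy is accounted lazily
    (only when a strategy's player count changes), so the run is linear in
    the number of encounters.
    """
    n_strat = strategy_net.n_nodes
    if n_strat < 1:
        raise ValueError("strategy network is empty")
    rng = np.random.default_rng(config.seed)
    n_players, m = config.n_players, config.n_encounters

    win = np.zeros((n_strat, n_strat), dtype=bool)
    for i, j in strategy_net.edges:
        if config.source_wins:
            win[i, j] = True
        else:
            win[j, i] = True
    win = win.tolist()  # plain lists keep the encounter loop cheap

    strategies = rng.integers(0, n_strat, size=n_players).tolist()
    counts = np.bincount(strategies, minlength=n_strat).astype(float).tolist()
    p1 = rng.integers(0, n_players, size=m)
    p2 = (p1 + 1 + rng.integers(0, n_players - 1, size=m)) % n_players
    coin = rng.random(size=m) < 0.5
    p1 = p1.tolist()
    p2 = p2.tolist()
    coin = coin.tolist()

    occupancy = [0.0] * n_strat
    last = [0] * n_strat  # first encounter index not yet credited

    for t in range(m):
        a, b = p1[t], p2[t]
        sa, sb = strategies[a], strategies[b]
        if sa == sb:
            continue
        ab, ba = win[sa][sb], win[sb][sa]
        if ab and ba:
            ab = coin[t]
            ba = not ab
        if ab:  # sa beats sb: player b adopts sa
            loser_player, winner_strat, loser_strat = b, sa, sb
        elif ba:
            loser_player, winner_strat, loser_strat = a, sb, sa
        else:
            continue
        # the change takes effect from encounter t+1 onwards
        occupancy[winner_strat] += counts[winner_strat] * (t + 1 - last[winner_strat])
        occupancy[loser_strat] += counts[loser_strat] * (t + 1 - last[loser_strat])
        last[winner_strat] = last[loser_strat] = t + 1
        counts[winner_strat] += 1
        counts[loser_strat] -= 1
        strategies[loser_player] = winner_strat

    for s in range(n_strat):
        occupancy[s] += counts[s] * (m - last[s])
    p = np.asarray(occupancy) / (float(m) * n_players)
    assert abs(p.sum() - 1.0) < 1e-9
    return PlayRecord(play_probability=p)


def pagerank(net: DirectedNetwork, damping: float = 0.85, reverse: bool = False) -> np.ndarray:
    """Standard PageRank (uniform teleportation); ``reverse=True`` runs on the
    edge-reversed graph so that emitters score high.  Sums to 1."""
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie in (0, 1)")
    g = net.to_networkx()
    if reverse:
        g = g.reverse()
    scores = nx.pagerank(g, alpha=damping)
    return np.array([scores[i] for i in range(net.n_nodes)])


def centrality_rankings(
    net: DirectedNetwork, levels: TrophicLevels, damping: float = 0.85
) -> dict[str, np.ndarray]:
    """Four deterministic node orderings, most-influential first.

    Trophic level ascends (low level = influential); reversed-graph PageRank,
    out-degree and imbalance ``k_out - k_in`` descend.  Ties break by node
    index.
    """
    in_deg, out_deg = degrees(net)
    idx = np.arange(net.n_nodes)
    return {
        "trophic_level": np.lexsort((idx, levels.h)),
        "pagerank": np.lexsort((idx, -pagerank(net, damping=damping, reverse=True))),
        "out_degree": np.lexsort((idx, -out_deg)),
        "imbalance": np.lexsort((idx, -(out_deg - in_deg))),
    }


def cumulative_play_curve(ranking: np.ndarray, record: PlayRecord) -> np.ndarray:
    """Entry ``k``: total play probability of the top ``k+1`` ranked
    strategies.  Non-decreasing with final entry 1."""
    ranking = np.asarray(ranking)
    p = record.play_probability
    if ranking.shape != p.shape or not np.array_equal(np.sort(ranking), np.arange(len(p))):
        raise ValueError("ranking must be a permutation of all strategies")
    return np.cumsum(p[ranking])


def curve_area(curve: np.ndarray) -> float:
    """Normalized area under a cumulative play curve (mean of its entries)."""
    return float(np.mean(curve))
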