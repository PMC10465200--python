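"""Influence dynamics on directed networks.

Three processes probe how a perturbation applied to the lowest-trophic-level
nodes spreads through a network:

* **Majority vote** — spins in {-1, +1}; each parallel sweep sets a node to
  the sign of the summed states of its *in*-neighbours (a zero sum or an
  empty in-neighbourhood keeps the previous state).
* **Voter model** — each node copies the state of one in-neighbour chosen
  uniformly at random per parallel sweep (asynchronous single-node updates
  available behind a flag).
* **Kuramoto oscillators** — phases evolve as

      dtheta_i/dt = omega_i + (K / k_in_i) * sum_j A_ji sin(theta_j - theta_i)

  from identical initial phases, with the coupling normalized by in-degree.
  Mean node frequency is estimated from phase differences sampled over the
  latter half of the run.

Phase synchrony is summarized by the order parameter
``r = |mean_i exp(i * theta_i)|`` in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .graph_core import DirectedNetwork, degrees
from .trophic import TrophicLevels

__all__ = [
    "KuramotoConfig",
    "DynamicsResult",
    "lowest_level_nodes",
    "spin_state",
    "majority_vote_run",
    "voter_run",
    "kuramoto_run",
    "phase_order_parameter",
]


@dataclass(frozen=True)
class KuramotoConfig:
    """Coupling ``K``, natural frequencies (rad/time), duration and sampling."""

    coupling: float
    omegas: np.ndarray
    t_end: float = 20.0
    n_samples: int = 50
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self):
        if self.coupling <= 0:
            raise ValueError("coupling must be positive")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")


@dataclass(frozen=True)
class DynamicsResult:
    """Outcome of one simulation.

    ``final_state`` holds spins (discrete dynamics) or per-node mean
    frequencies (Kuramoto); ``mean_state`` is its average.  ``order_parameter``
    and ``frequency_std`` are Kuramoto-only.  ``trajectory_summary`` records
    the mean state at each recorded step/sample.
    """

    final_state: np.ndarray
    mean_state: float
    order_parameter: float | None = None
    frequency_std: float | None = None
    trajectory_summary: np.ndarray | None = None


def lowest_level_nodes(levels: TrophicLevels, fraction: float) -> np.ndarray:
    """Indices of the ``floor(fraction * N)`` nodes of smallest trophic level.

    Ties are broken by ascending node index (stable sort), making the
    selection deterministic.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(levels.h)
    k = int(np.floor(fraction * n))
    if k < 1:
        raise ValueError("fraction * n_nodes must be at least 1")
    order = np.argsort(levels.h, kind="stable")
    return np.sort(order[:k])


def spin_state(n_nodes: int, minus_nodes) -> np.ndarray:
    """All-(+1) spin vector with the given nodes set to -1."""
    s = np.ones(n_nodes, dtype=np.int64)
    s[np.asarray(list(minus_nodes), dtype=np.int64)] = -1
    return s


def _check_spins(net: DirectedNetwork, s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=np.int64)
    if s.shape != (net.n_nodes,) or not np.all(np.abs(s) == 1):
        raise ValueError("initial state must be a vector of +/-1 per node")
    return s


def majority_vote_run(
    net: DirectedNetwork, initial: np.ndarray, n_steps: int
) -> DynamicsResult:
    """Run ``n_steps`` synchronous majority-vote sweeps.

    The update is deterministic, so a fixed point or a period-2 cycle is
    detected and the remaining sweeps are short-circuited (respecting parity
    for the 2-cycle).
    """
    s = _check_spins(net, initial).copy()
    at = net.adjacency.T.tocsr()
    means = [float(s.mean())]
    prev = None
    for step in range(n_steps):
        field_ = at @ s
        nxt = np.where(field_ > 0, 1, np.where(field_ < 0, -1, s))
        if np.array_equal(nxt, s):  # fixed point
            s = nxt
            break
        if prev is not None and np.array_equal(nxt, prev):  # period-2 cycle
            remaining = n_steps - (step + 1)
            if remaining % 2 == 0:
                s = nxt.astype(np.int64)
                means.append(float(s.mean()))
            break
        prev, s = s, nxt.astype(np.int64)
        means.append(float(s.mean()))
    return DynamicsResult(
        final_state=s, mean_state=float(s.mean()),
        trajectory_summary=np.array(means),
    )


def voter_run(
    net: DirectedNetwork,
    initial: np.ndarray,
    n_steps: int,
    seed: int | np.random.Generator | None = None,
    mode: str = "parallel",
) -> DynamicsResult:
    """Run the voter model: copy the state of a random in-neighbour.

    ``mode="parallel"`` (default) performs ``n_steps`` synchronous sweeps;
    ``mode="async"`` performs ``n_steps * N`` single-node updates, each on a
    uniformly chosen node.  Nodes without in-neighbours keep their state.
    """
    if mode not in ("parallel", "async"):
        raise ValueError("mode must be 'parallel' or 'async'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = _check_spins(net, initial).copy()
    at = net.adjacency.T.tocsr()  # row i lists the in-neighbours of i
    indptr, indices = at.indptr, at.indices
    indeg = np.diff(indptr)
    active = indeg > 0
    means = [float(s.mean())]
    if mode == "parallel":
        for _ in range(n_steps):
            if np.all(s == s[0]):
                break  # consensus is absorbing
            pick = indptr[:-1] + (rng.random(net.n_nodes) * np.maximum(indeg, 1)).astype(np.int64)
            nxt = s.copy()
            nxt[active] = s[indices[pick[active]]]
            s = nxt
            means.append(float(s.mean()))
    else:
        nodes = rng.integers(0, net.n_nodes, size=n_steps * net.n_nodes)
        draws = rng.random(size=len(nodes))
        for t, i in enumerate(nodes):
            if indeg[i]:
                s[i] = s[indices[indptr[i] + int(draws[t] * indeg[i])]]
            if (t + 1) % net.n_nodes == 0:
                means.append(float(s.mean()))
    return DynamicsResult(
        final_state=s, mean_state=float(s.mean()),
        trajectory_summary=np.array(means),
    )


def phase_order_parameter(theta: np.ndarray) -> float:
    """Kuramoto order parameter ``r = |mean exp(i theta)|`` in [0, 1]."""
    return float(np.abs(np.exp(1j * np.asarray(theta)).mean()))


def kuramoto_run(net: DirectedNetwork, config: KuramotoConfig) -> DynamicsResult:
    """Integrate in-degree-normalized Kuramoto dynamics from identical phases.

    Nodes with no in-neighbours (basal nodes) evolve at their natural
    frequency (zero coupling term).  Phases are kept unwrapped so per-node
    frequencies are plain phase differences over time differences, sampled at
    ``n_samples`` evenly spaced times over the latter half of the run.
    """
    omegas = np.asarray(config.omegas, dtype=float)
    if omegas.shape != (net.n_nodes,):
        raise ValueError("omegas must have one entry per node")
    at = net.adjacency.T.tocsr()
    indeg = np.asarray(degrees(net)[0], dtype=float)
    gain = np.zeros(net.n_nodes)
    nz = indeg > 0
    gain[nz] = config.coupling / indeg[nz]

    def rhs(_t, theta):
        sin_t, cos_t = np.sin(theta), np.cos(theta)
        # sum_j A_ji sin(theta_j - theta_i), expanded via angle addition
        coupling = cos_t * (at @ sin_t) - sin_t * (at @ cos_t)
        return omegas + gain * coupling

    t_samples = np.linspace(config.t_end / 2.0, config.t_end, config.n_samples)
    sol = solve_ivp(
        rhs,
        (0.0, config.t_end),
        np.zeros(net.n_nodes),
        t_eval=t_samples,
        rtol=config.rtol,
        atol=config.atol,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"Kuramoto integration failed: {sol.message}")
    theta = sol.y  # (n_nodes, n_samples), unwrapped by construction
    dt = np.diff(t_samples)
    freqs = (np.diff(theta, axis=1) / dt).mean(axis=1)  # per-node frequency
    return DynamicsResult(
        final_state=freqs,
        mean_state=float(freqs.mean()),
        order_parameter=phase_order_parameter(theta[:, -1]),
        frequency_std=float(freqs.std()),
        trajectory_summary=theta.mean(axis=0),
    )
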