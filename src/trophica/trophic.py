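"""Trophic levels and trophic incoherence of directed networks.

Trophic analysis assigns every node a hierarchy coordinate ``h_i`` (its
*trophic level*) by solving the linear system

    Lambda h = v,      Lambda = diag(k_in + k_out) - A - A^T,
    v_i = k_in_i - k_out_i,

which is the stationarity condition of the quadratic *trophic incoherence*

    F = (1 / m) * sum over edges (i -> j) of (h_j - h_i - 1)^2,

where ``m`` is the edge count.  ``F`` is 0 for a perfect hierarchy (directed
path) and 1 for a balanced graph (directed cycle).  The Laplacian is singular
— levels are defined up to a constant per weakly connected component — so one
node per component is pinned to zero during the solve and the assembled
solution is shifted so the global minimum level is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_core import DirectedNetwork, degrees, weakly_connected_components

__all__ = [
    "TrophicLevels",
    "IncoherenceSummary",
    "imbalance_vector",
    "trophic_laplacian",
    "trophic_levels",
    "edge_level_differences",
    "incoherence",
    "eta_to_F",
    "predicted_F_from_temperature",
]

#: default relative residual tolerance of the level solve
DEFAULT_RTOL = 1e-8


@dataclass(frozen=True)
class TrophicLevels:
    """Per-node trophic levels, min-shifted so ``h.min() == 0``.

    ``pinned_node`` records the node anchored to zero during the (singular)
    solve of the first weakly connected component.
    """

    h: np.ndarray
    pinned_node: int


@dataclass(frozen=True)
class IncoherenceSummary:
    """Trophic incoherence ``F`` with the edge-level-difference statistics.

    ``mu`` and ``sigma`` are the mean and (population) standard deviation of
    ``h_j - h_i`` over edges ``i -> j``; ``eta = sigma / mu`` is the
    coefficient of variation used by the legacy incoherence parameter.
    """

    F: float
    eta: float
    mu: float
    sigma: float


def imbalance_vector(net: DirectedNetwork) -> np.ndarray:
    """``v_i = k_in_i - k_out_i``; components sum to zero."""
    in_deg, out_deg = degrees(net)
    return (in_deg - out_deg).astype(float)


def trophic_laplacian(net: DirectedNetwork, sparse: bool = False):
    """Symmetric Laplacian ``diag(k_in + k_out) - A - A^T`` (zero row sums)."""
    a = net.adjacency
    in_deg, out_deg = degrees(net)
    lam = sp.diags((in_deg + out_deg).astype(float)) - a - a.T
    return lam.tocsr() if sparse else lam.toarray()


def trophic_levels(
    net: DirectedNetwork,
    rtol: float = DEFAULT_RTOL,
    on_edgeless: str = "error",
) -> TrophicLevels:
    """Solve for the trophic levels of ``net``.

    The system is solved independently on each weakly connected component
    (pinning the lowest-index node of the component to zero renders the
    component Laplacian positive definite), then the full vector is shifted so
    the global minimum level is zero.

    Parameters
    ----------
    rtol:
        Relative residual tolerance: the solve must satisfy
        ``||Lambda h - v|| <= rtol * ||v|| + 1e-12`` on every component.
    on_edgeless:
        ``"error"`` (default) raises for a component with no edges, where
        levels are undefined; ``"zero"`` assigns such components level 0
        (used internally by the network generator, whose seed graphs may
        contain isolated basal nodes).

    Raises
    ------
    ValueError
        If a weak component has no edges (``on_edgeless="error"``) or the
        residual tolerance is not met.
    """
    if on_edgeless not in ("error", "zero"):
        raise ValueError("on_edgeless must be 'error' or 'zero'")
    n = net.n_nodes
    lam = trophic_laplacian(net, sparse=True).tocsr()
    v = imbalance_vector(net)
    h = np.zeros(n)
    pinned_global = None
    for comp in weakly_connected_components(net):
        idx = np.array(sorted(comp), dtype=np.int64)
        sub = lam[np.ix_(idx, idx)]
        if sub.nnz == 0:
            if on_edgeless == "error":
                raise ValueError(
                    f"weakly connected component {sorted(comp)[:5]}... has no "
                    "edges; trophic levels are undefined"
                )
            continue  # h stays 0 on this component
        pin = idx[0]
        if pinned_global is None or pin < pinned_global:
            pinned_global = pin
        free = idx[1:]
        v_sub = v[idx]
        if len(free) > 0:
            reduced = sub[1:, 1:].tocsc()
            rhs = v_sub[1:]  # pinned value is 0, nothing to move across
            if len(free) <= 400:
                sol = np.linalg.solve(reduced.toarray(), rhs)
            else:
                sol = spla.spsolve(reduced, rhs)
            h[free] = sol
        resid = np.linalg.norm(sub @ h[idx] - v_sub)
        if resid > rtol * np.linalg.norm(v_sub) + 1e-12:
            raise ValueError(
                f"trophic level solve did not meet tolerance: residual "
                f"{resid:.3e} > rtol {rtol:.1e} * ||v||"
            )
    h -= h.min()
    if pinned_global is None:  # every component edgeless (on_edgeless="zero")
        pinned_global = 0
    return TrophicLevels(h=h, pinned_node=int(pinned_global))


def edge_level_differences(net: DirectedNetwork, h: np.ndarray) -> np.ndarray:
    """``h_j - h_i`` over edges ``i -> j`` in deterministic edge order."""
    e = net.sorted_edges()
    if len(e) == 0:
        raise ValueError("network has no edges")
    return h[e[:, 1]] - h[e[:, 0]]


def incoherence(
    net: DirectedNetwork, levels: TrophicLevels | None = None
) -> IncoherenceSummary:
    """Trophic incoherence ``F`` and edge-difference statistics for ``net``.

    For balanced graphs every level difference is zero, so ``mu = sigma = 0``;
    ``eta`` is reported as ``inf`` there (consistent with ``F = 1`` through
    ``F = eta^2 / (1 + eta^2)``).
    """
    if levels is None:
        levels = trophic_levels(net)
    d = edge_level_differences(net, levels.h)
    F = float(np.mean((d - 1.0) ** 2))
    mu = float(np.mean(d))
    sigma = float(np.std(d))
    eta = math.inf if mu == 0.0 else sigma / mu
    return IncoherenceSummary(F=F, eta=eta, mu=mu, sigma=sigma)


def eta_to_F(eta: float) -> float:
    """Convert the legacy incoherence parameter ``eta = sigma/mu`` to ``F``.

    ``F = eta^2 / (1 + eta^2)``, monotone increasing, in ``[0, 1)`` for finite
    ``eta`` and 1 at ``eta = inf``.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    return 1.0 - 1.0 / (1.0 + eta * eta)


def predicted_F_from_temperature(t_gen: float) -> float:
    """Analytic approximation ``F ~ T_gen / (1 + T_gen)`` for the generator.

    On a log10 temperature axis this is a sigmoid, which is why log-spaced
    generation temperatures sweep the whole incoherence range.
    """
    if t_gen <= 0:
        raise ValueError("t_gen must be positive")
    return t_gen / (1.0 + t_gen)
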