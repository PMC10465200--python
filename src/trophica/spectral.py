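"""Eigenvector localization and perturbation sensitivity of adjacency matrices.

Four summary statistics connect a network's spectral structure to its trophic
coherence:

* **Mean inverse participation ratio (IPR)** of the L2-normalized right
  eigenvectors: ``sum |psi_i|^4 / (sum |psi_i|^2)^2``, in ``[1/N, 1]``;
  1 for a one-hot vector, ``1/N`` for a uniform one.  Coherent networks have
  localized eigenvectors (high IPR).
* **Mean eigenvector entropy** of the L1-normalized moduli:
  ``-(1/ln N) * sum |phi_i| ln |phi_i|`` with ``0 ln 0 := 0``, in ``[0, 1]``;
  0 when concentrated in one node, 1 when uniform.
* **Left/right principal-eigenvector overlap**: dot product of the
  elementwise-modulus, L2-normalized principal eigenvectors of ``A``
  ("emitting" centrality) and ``A^T`` ("receiving" centrality); near 0 when a
  hierarchy separates emitters from receivers, near 1 for balanced networks.
* **Scaled pseudospectral radius**: ``(rho_eps(A) - rho(A)) / eps`` where
  ``rho_eps`` is the radius of the eps-pseudospectrum
  ``{z : sigma_min(zI - A) <= eps}`` (spectral-norm perturbations).  Order 1
  for normal matrices; large for the highly non-normal adjacencies of
  coherent networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as la
import scipy.sparse.linalg as spla

from .graph_core import DirectedNetwork

__all__ = [
    "SpectralSummary",
    "inverse_participation_ratio",
    "eigenvector_entropy",
    "mean_ipr",
    "mean_entropy",
    "principal_lr_overlap",
    "pseudospectral_radius",
    "spectral_summary",
]


@dataclass(frozen=True)
class SpectralSummary:
    mean_ipr: float
    mean_entropy: float
    lr_overlap: float
    pseudospectral_radius_scaled: float
    epsilon: float


def inverse_participation_ratio(vec: np.ndarray) -> float:
    """IPR of one vector (moduli taken, L2 normalization built in)."""
    a = np.abs(np.asarray(vec, dtype=complex))
    s2 = np.sum(a**2)
    if s2 == 0:
        raise ValueError("zero vector has no IPR")
    return float(np.sum(a**4) / s2**2)


def eigenvector_entropy(vec: np.ndarray) -> float:
    """Normalized Shannon entropy of the L1-normalized moduli of ``vec``."""
    a = np.abs(np.asarray(vec, dtype=complex))
    s1 = a.sum()
    if s1 == 0:
        raise ValueError("zero vector has no entropy")
    p = a / s1
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum() / np.log(len(a)))


def _as_dense(net) -> np.ndarray:
    if isinstance(net, DirectedNetwork):
        return net.adjacency.toarray()
    return np.asarray(net, dtype=float)


def _right_eigvecs(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    _, vecs = np.linalg.eig(a)
    return vecs


def mean_ipr(net) -> float:
    """Average IPR over all right adjacency eigenvectors; in ``[1/N, 1]``."""
    vecs = _right_eigvecs(_as_dense(net))
    return float(np.mean([inverse_participation_ratio(vecs[:, k]) for k in range(vecs.shape[1])]))


def mean_entropy(net) -> float:
    """Average normalized entropy over all right adjacency eigenvectors."""
    vecs = _right_eigvecs(_as_dense(net))
    return float(np.mean([eigenvector_entropy(vecs[:, k]) for k in range(vecs.shape[1])]))


def _principal_vector_dense(a: np.ndarray) -> tuple[complex, np.ndarray]:
    vals, vecs = np.linalg.eig(a)
    # largest modulus; ties resolved toward the largest real part
    order = np.lexsort((vals.real, np.abs(vals)))
    k = order[-1]
    return vals[k], vecs[:, k]


def _principal_vector(a: np.ndarray, sparse_threshold: int = 300) -> tuple[complex, np.ndarray]:
    n = a.shape[0]
    if n >= sparse_threshold:
        try:
            vals, vecs = spla.eigs(a, k=3, which="LM")
            order = np.lexsort((vals.real, np.abs(vals)))
            k = order[-1]
            return vals[k], vecs[:, k]
        except (spla.ArpackNoConvergence, RuntimeError):
            pass
    return _principal_vector_dense(a)


def principal_lr_overlap(net) -> float:
    """Scalar product of the modulus-L2-normalized principal right eigenvectors
    of ``A`` and of ``A^T``; in ``[0, 1]``.

    Warns when the spectral radius is numerically zero (nilpotent adjacency),
    where the principal eigenpair — and hence the overlap — is ill-defined.
    """
    a = _as_dense(net)
    lam_r, right = _principal_vector(a)
    _, left = _principal_vector(a.T)
    if abs(lam_r) < 1e-10:
        warnings.warn(
            "spectral radius is numerically zero; left/right overlap is "
            "ill-defined for a nilpotent adjacency",
            RuntimeWarning,
        )
    r = np.abs(right)
    l_ = np.abs(left)
    return float(np.dot(l_ / np.linalg.norm(l_), r / np.linalg.norm(r)))


# -- pseudospectral radius -------------------------------------------------


class _SigmaMin:
    """Smallest singular value of ``zI - A`` via the Schur form.

    ``sigma_min(zI - A) = sigma_min(zI - T)`` for the (complex, triangular)
    Schur factor ``T``, so each evaluation is inverse power iteration with two
    triangular solves per step instead of a full SVD.  The iteration vector is
    warm-started between nearby evaluations.
    """

    def __init__(self, a: np.ndarray):
        self.t, _ = la.schur(a.astype(complex), output="complex")
        self.n = a.shape[0]
        self._x = None

    def __call__(self, z: complex, rtol: float = 1e-10, maxiter: int = 300) -> float:
        m = -self.t.copy()
        m[np.diag_indices(self.n)] += z
        x = self._x
        if x is None:
            x = np.ones(self.n, dtype=complex) / np.sqrt(self.n)
        lam_prev = 0.0
        with np.errstate(all="ignore"):
            for _ in range(maxiter):
                try:
                    y = la.solve_triangular(m, x, trans="C", check_finite=False)
                    w = la.solve_triangular(m, y, check_finite=False)
                except la.LinAlgError:
                    return 0.0
                norm_w = np.linalg.norm(w)
                if not np.isfinite(norm_w) or norm_w == 0.0:
                    return 0.0
                lam = norm_w  # Rayleigh growth factor of (M M^H)^-1 iteration
                x = w / norm_w
                if abs(lam - lam_prev) <= rtol * lam:
                    break
                lam_prev = lam
        self._x = x
        return float(1.0 / np.sqrt(lam))


def pseudospectral_radius(
    net,
    epsilon: float = 1e-3,
    method: str = "grid",
    n_angles: int = 64,
    n_samples: int = 20,
    seed: int | None = 0,
) -> float:
    """Scaled pseudospectral radius ``(rho_eps(A) - rho(A)) / epsilon``.

    ``method="grid"`` (default, deterministic) searches radially: along rays
    through the largest-modulus eigenvalues and a sweep of ``n_angles``
    directions it locates, by coarse scan plus bisection, the largest radius
    at which ``sigma_min(zI - A) <= epsilon``.  ``method="sampled"`` takes the
    maximum spectral radius of ``A + E`` over ``n_samples`` random
    perturbations of spectral norm ``epsilon`` — a lower bound on the grid
    value.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    a = _as_dense(net)
    eigvals = np.linalg.eigvals(a)
    rho = float(np.max(np.abs(eigvals))) if len(eigvals) else 0.0

    if method == "sampled":
        rng = np.random.default_rng(seed)
        best = rho
        for _ in range(n_samples):
            e = rng.standard_normal(a.shape)
            e *= epsilon / np.linalg.norm(e, 2)
            best = max(best, float(np.max(np.abs(np.linalg.eigvals(a + e)))))
        return (best - rho) / epsilon
    if method != "grid":
        raise ValueError("method must be 'grid' or 'sampled'")

    smin = _SigmaMin(a)
    r_hi = float(np.linalg.norm(a, 2)) + 2.0 * epsilon  # sigma_min > eps beyond
    xtol = 1e-9 * max(1.0, r_hi)
    best = rho

    def bisect(phi: float, lo: float, hi: float) -> float:
        # invariant: sigma_min <= eps at lo, > eps at hi
        direction = np.exp(1j * phi)
        while hi - lo > xtol:
            mid = 0.5 * (lo + hi)
            if smin(mid * direction) <= epsilon:
                lo = mid
            else:
                hi = mid
        return lo

    rays: list[tuple[float, bool]] = []
    if rho > 0:
        top = eigvals[np.abs(eigvals) >= rho * (1.0 - 1e-9)]
        rays += [(float(np.angle(z)), True) for z in top]
    else:
        rays.append((0.0, True))
    rays += [(phi, False) for phi in np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)]

    n_scan = 16
    for phi, through_eig in rays:
        smin._x = None  # fresh warm start per ray
        if through_eig:
            # z = rho * e^{i phi} is (numerically) an eigenvalue: sigma_min ~ 0
            best = max(best, bisect(phi, max(best, rho), r_hi))
            continue
        if r_hi - best <= xtol:
            continue
        grid = np.linspace(r_hi, best, n_scan)
        direction = np.exp(1j * phi)
        for k in range(1, n_scan):
            if smin(grid[k] * direction) <= epsilon:
                best = max(best, bisect(phi, grid[k], grid[k - 1]))
                break
    return (best - rho) / epsilon


def spectral_summary(net, epsilon: float = 1e-3) -> SpectralSummary:
    """All four spectral metrics for one network."""
    a = _as_dense(net)
    vecs = _right_eigvecs(a)
    iprs = [inverse_participation_ratio(vecs[:, k]) for k in range(vecs.shape[1])]
    ents = [eigenvector_entropy(vecs[:, k]) for k in range(vecs.shape[1])]
    return SpectralSummary(
        mean_ipr=float(np.mean(iprs)),
        mean_entropy=float(np.mean(ents)),
        lr_overlap=principal_lr_overlap(a),
        pseudospectral_radius_scaled=pseudospectral_radius(a, epsilon=epsilon),
        epsilon=epsilon,
    )
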