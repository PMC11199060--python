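"""Similarity network fusion: nonlinear cross-diffusion of two or more views.

The construction follows the canonical SNF recipe (scaled-exponential
affinity kernel, full and K-nearest-neighbour transition kernels, iterative
cross-diffusion).  The source material cites SNF without printing kernel
formulas or hyperparameters, so every constant here is config-exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import CohortError, SimilarityNetwork

logger = logging.getLogger("idsn")


@dataclass
class FusionParams:
    k: int = 20
    mu: float = 0.5
    iterations: int = 20
    eps_reg: float = 1e-8

    def __post_init__(self) -> None:
        if self.k < 1:
            raise CohortError("K must be >= 1")
        if self.mu <= 0:
            raise CohortError("mu must be positive")
        if self.iterations < 1:
            raise CohortError("iteration count must be >= 1")
        if self.eps_reg <= 0:
            raise CohortError("eps_reg must be positive")


@dataclass
class FusionDiagnostics:
    """Per-iteration mean absolute change of each view's status matrix."""

    changes: list[list[float]] = field(default_factory=list)  # [iter][view]
    converged: bool = False
    tolerance: float = 1e-6


def similarity_to_distance(net: SimilarityNetwork) -> np.ndarray:
    """d_ij = sqrt(2 * (1 - s_ij)); zero diagonal, symmetric."""
    if net.scale != "similarity":
        raise CohortError("similarity_to_distance requires similarity scale")
    s = net.matrix
    if s.size and (s.min() < -1e-12 or s.max() > 1 + 1e-12):
        raise CohortError("similarities outside [0,1]")
    d = np.sqrt(np.maximum(2.0 * (1.0 - np.clip(s, 0.0, 1.0)), 0.0))
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def affinity_matrix(d: np.ndarray, params: FusionParams) -> np.ndarray:
    """Scaled-exponential kernel W_ij = exp(-d_ij^2 / (mu * eps_ij)).

    eps_ij averages the mean K-NN distance of i, of j, and d_ij itself;
    ``eps_reg`` keeps it positive for duplicate points.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if params.k >= n:
        raise CohortError(f"K={params.k} must be < n={n}")
    if np.max(np.abs(d - d.T)) > 1e-10 or np.max(np.abs(np.diag(d))) > 1e-12:
        raise CohortError("distance matrix must be symmetric with zero diagonal")
    # mean distance of each point to its K nearest neighbours (self excluded)
    sorted_d = np.sort(d, axis=1)[:, 1:params.k + 1]
    knn_mean = sorted_d.mean(axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + d) / 3.0 + params.eps_reg
    W = np.exp(-(d ** 2) / (params.mu * eps))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return W


def full_kernel(W: np.ndarray, ids: list[str] | None = None) -> np.ndarray:
    """Row-stochastic status matrix: P_ii = 1/2, off-diagonal mass 1/2."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    isolated = np.flatnonzero(rowsum <= 0)
    if isolated.size:
        names = [ids[i] if ids else str(i) for i in isolated]
        raise CohortError(f"isolated nodes with zero off-diagonal row: {names}")
    P = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def local_kernel(W: np.ndarray, k: int, ids: list[str] | None = None) -> np.ndarray:
    """Sparse kernel over each point's K nearest neighbours by affinity.

    Ties at the K-th neighbour are broken by drug id order (lexicographic)
    for cross-platform determinism.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if k >= n:
        raise CohortError(f"K={k} must be < n={n}")
    order_key = np.array(ids) if ids is not None else np.arange(n).astype(str)
    S = np.zeros_like(W)
    for i in range(n):
        cand = np.array([j for j in range(n) if j != i])
        # descending affinity, ties by id order
        rank = np.lexsort((order_key[cand], -W[i, cand]))
        nbrs = cand[rank[:k]]
        denom = W[i, nbrs].sum()
        if denom <= 0:
            names = ids[i] if ids else str(i)
            raise CohortError(f"node {names}: zero affinity to all neighbours")
        S[i, nbrs] = W[i, nbrs] / denom
    return S


def _renormalize(M: np.ndarray) -> np.ndarray:
    """Re-apply the full-kernel normalization to a diffused status matrix."""
    off = M.copy()
    np.fill_diagonal(off, 0.0)
    rowsum = off.sum(axis=1)
    rowsum[rowsum <= 0] = 1.0
    P = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def snf(
    views: list[SimilarityNetwork],
    params: FusionParams | None = None,
) -> tuple[SimilarityNetwork, FusionDiagnostics]:
    """Fuse >= 2 views over the same ordered id set into one network.

    Each iteration diffuses every view's status matrix through its own
    sparse local kernel against the average of the other views, then
    renormalizes.  The output is the view average, symmetrized, with
    off-diagonal entries rescaled by their maximum and unit diagonal.
    """
    params = params or FusionParams()
    if len(views) < 2:
        raise CohortError("snf requires at least two views")
    ids = views[0].ids
    for v in views[1:]:
        if v.ids != ids:
            differing = sorted(set(v.ids) ^ set(ids))
            raise CohortError(f"views disagree on ids: {differing or 'order'}")

    Ws = []
    for v in views:
        if v.scale == "similarity":
            d = similarity_to_distance(v)
            Ws.append(affinity_matrix(d, params))
        else:
            Ws.append(v.matrix.copy())
    Ps = [full_kernel(W, ids) for W in Ws]
    Ss = [local_kernel(W, params.k, ids) for W in Ws]

    m = len(views)
    diag = FusionDiagnostics()
    for _ in range(params.iterations):
        new_Ps = []
        for v in range(m):
            others = [Ps[u] for u in range(m) if u != v]
            mean_other = np.mean(others, axis=0)
            new_Ps.append(_renormalize(Ss[v] @ mean_other @ Ss[v].T))
        changes = [
            float(np.mean(np.abs(new_Ps[v] - Ps[v]))) for v in range(m)
        ]
        diag.changes.append(changes)
        Ps = new_Ps
    diag.converged = bool(max(diag.changes[-1]) < diag.tolerance)

    fused = np.mean(Ps, axis=0)
    fused = (fused + fused.T) / 2.0
    off = fused.copy()
    np.fill_diagonal(off, 0.0)
    peak = off.max()
    if peak > 0:
        fused = off / peak
    else:
        fused = off
    np.fill_diagonal(fused, 1.0)
    fused = np.clip(fused, 0.0, 1.0)
    net = SimilarityNetwork(ids=list(ids), matrix=fused, source="fused")
    return net, diag
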