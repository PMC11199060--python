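"""Spectral clustering of similarity networks and clustering-validity metrics.

External metrics (ARI, NMI) are implemented from the contingency table so
test suites can check them against independent pair-counting oracles.
Centroid-based internal indices (Davies-Bouldin, Calinski-Harabasz) are
computed on the spectral embedding, which provides the vector space they
require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from .core_io import AnnotationTable, CohortError, SimilarityNetwork

logger = logging.getLogger("idsn")


@dataclass
class ClusteringResult:
    labels: dict[str, int]
    k: int
    embedding: np.ndarray
    eigenvalues: np.ndarray  # first k+1 Laplacian eigenvalues, non-decreasing
    seed: int

    def label_array(self, ids: list[str]) -> np.ndarray:
        return np.array([self.labels[d] for d in ids], dtype=int)


@dataclass
class EvaluationReport:
    """Metric grid: one internal row per network, one external row per
    (network, annotation scheme)."""

    internal: list[dict] = field(default_factory=list)
    external: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.meta.items():
                fh.write(f"#{key}\t{value}\n")
            fh.write("kind\tnetwork\tscheme\tmetric\tvalue\tcoverage\n")
            for row in self.internal:
                for metric in ("silhouette", "davies_bouldin", "calinski_harabasz"):
                    fh.write(
                        f"internal\t{row['network']}\t-\t{metric}\t"
                        f"{row[metric]:.10g}\t{row['n']}\n"
                    )
            for row in self.external:
                for metric in ("ari", "nmi"):
                    fh.write(
                        f"external\t{row['network']}\t{row['scheme']}\t{metric}\t"
                        f"{row[metric]:.10g}\t{row['coverage']}\n"
                    )


def _laplacian_spectrum(net: SimilarityNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the symmetric normalized Laplacian.

    Returns (eigenvalues ascending, eigenvectors as columns).
    """
    W = net.matrix.copy()
    np.fill_diagonal(W, 0.0)
    n_comp, comp = connected_components(W > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp).tolist()
        raise CohortError(
            f"network is disconnected: {n_comp} components of sizes {sizes}"
        )
    deg = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(net.n) - (inv_sqrt[:, None] * W) * inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    evals, evecs = np.linalg.eigh(L)
    return evals, evecs


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign: largest-magnitude entry positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        idx = int(np.argmax(np.abs(out[:, j])))
        if out[idx, j] < 0:
            out[:, j] = -out[:, j]
    return out


def spectral_embedding(net: SimilarityNetwork, k: int) -> np.ndarray:
    """First k normalized-Laplacian eigenvectors, rows scaled to unit length."""
    if k < 1 or k > net.n:
        raise CohortError(f"k={k} out of range for n={net.n}")
    evals, evecs = _laplacian_spectrum(net)
    emb = _fix_signs(evecs[:, :k])
    norms = np.linalg.norm(emb, axis=1)
    norms[norms == 0] = 1.0
    return emb / norms[:, None]


def spectral_cluster(net: SimilarityNetwork, k: int, seed: int = 0) -> ClusteringResult:
    """K-means over the spectral embedding; labels relabelled by descending
    cluster size for determinism."""
    if k < 2:
        raise CohortError("k must be >= 2")
    if k > net.n:
        raise CohortError(f"k={k} exceeds n={net.n}")
    evals, evecs = _laplacian_spectrum(net)
    emb = _fix_signs(evecs[:, :k])
    norms = np.linalg.norm(emb, axis=1)
    norms[norms == 0] = 1.0
    emb = emb / norms[:, None]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(emb)
    labels = _relabel_by_size(raw)
    n_eval = min(k + 1, evals.size)
    return ClusteringResult(
        labels={d: int(l) for d, l in zip(net.ids, labels)},
        k=k,
        embedding=emb,
        eigenvalues=evals[:n_eval],
        seed=seed,
    )


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel 0..k-1 by descending cluster size; ties by first occurrence."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    first_seen = {int(u): int(np.argmax(labels == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-int(np.sum(labels == u)), first_seen[int(u)]))
    remap = {int(u): i for i, u in enumerate(order)}
    return np.array([remap[int(l)] for l in labels], dtype=int)


def eigengap_candidates(net: SimilarityNetwork, kmax: int) -> list[int]:
    """k values in [2, kmax] ranked by descending eigengap of the spectrum."""
    if kmax >= net.n:
        raise CohortError(f"kmax={kmax} must be < n={net.n}")
    if kmax < 2:
        raise CohortError("kmax must be >= 2")
    evals, _ = _laplacian_spectrum(net)
    gaps = {k: float(evals[k] - evals[k - 1]) for k in range(2, kmax + 1)}
    return sorted(gaps, key=lambda k: (-gaps[k], k))


def _as_arrays(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Accept parallel arrays or two dicts keyed by the same id set."""
    if isinstance(a, dict) or isinstance(b, dict):
        if set(a) != set(b):
            raise CohortError(
                f"label id mismatch: {sorted(set(a) ^ set(b))}"
            )
        keys = sorted(a)
        return (np.array([a[k] for k in keys]), np.array([b[k] for k in keys]))
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise CohortError(f"label arrays differ in length: {a.size} vs {b.size}")
    return a, b


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected pair-counting agreement between two labellings."""
    a, b = _as_arrays(a, b)
    n = a.size
    table = _contingency(a, b)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table.astype(float)).sum()
    sum_a = comb2(table.sum(axis=1).astype(float)).sum()
    sum_b = comb2(table.sum(axis=0).astype(float)).sum()
    total = comb2(float(n))
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def normalized_mutual_information(a, b, average: str = "geometric") -> float:
    """I(a;b) normalized by the (geometric by default) mean of entropies.

    Defined as 1.0 when both labellings are single-cluster, 0.0 when only
    one of them is.
    """
    a, b = _as_arrays(a, b)
    n = a.size
    table = _contingency(a, b).astype(float)
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
    hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
    if ha == 0 and hb == 0:
        return 1.0
    if ha == 0 or hb == 0:
        return 0.0
    pij = table / n
    mask = pij > 0
    mi = np.sum(pij[mask] * np.log(pij[mask] / np.outer(pa, pb)[mask]))
    mi = max(mi, 0.0)
    if average == "geometric":
        denom = np.sqrt(ha * hb)
    elif average == "arithmetic":
        denom = (ha + hb) / 2.0
    else:
        raise CohortError(f"unknown NMI average {average!r}")
    return float(min(mi / denom, 1.0))


def silhouette_score(net: SimilarityNetwork, labels) -> float:
    """Mean silhouette with distance 1 - similarity; singletons score 0."""
    if isinstance(labels, dict):
        lab = np.array([labels[d] for d in net.ids], dtype=int)
    else:
        lab = np.asarray(labels, dtype=int)
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise CohortError("silhouette requires >= 2 clusters")
    D = 1.0 - net.matrix
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    n = net.n
    scores = np.zeros(n)
    for i in range(n):
        own = lab[i]
        own_mask = lab == own
        if own_mask.sum() == 1:
            scores[i] = 0.0
            continue
        a = D[i, own_mask & (np.arange(n) != i)].mean()
        b = min(D[i, lab == other].mean() for other in uniq if other != own)
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def davies_bouldin(embedding: np.ndarray, labels) -> float:
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise CohortError("Davies-Bouldin requires >= 2 clusters")
    return float(davies_bouldin_score(np.asarray(embedding), labels))


def calinski_harabasz(embedding: np.ndarray, labels) -> float:
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise CohortError("Calinski-Harabasz requires >= 2 clusters")
    return float(calinski_harabasz_score(np.asarray(embedding), labels))


def benchmark_report(
    networks: list[SimilarityNetwork],
    annotations: list[AnnotationTable],
    k: int,
    seed: int = 0,
    network_names: list[str] | None = None,
) -> EvaluationReport:
    """Cluster every network and score it against every annotation scheme.

    Annotations covering fewer than 3 drugs of a network are skipped with a
    warning; external metrics are computed on the covered subset.
    """
    names = network_names or [net.source for net in networks]
    report = EvaluationReport(meta={"k": k, "seed": seed})
    for name, net in zip(names, networks):
        result = spectral_cluster(net, k=k, seed=seed)
        lab = result.label_array(net.ids)
        report.internal.append({
            "network": name,
            "n": net.n,
            "silhouette": silhouette_score(net, lab),
            "davies_bouldin": davies_bouldin(result.embedding, lab),
            "calinski_harabasz": calinski_harabasz(result.embedding, lab),
        })
        for annot in annotations:
            covered = [d for d in net.ids if d in annot.mapping]
            if len(covered) < 3:
                logger.warning(
                    "scheme %s covers %d drugs of network %s; skipped",
                    annot.scheme, len(covered), name,
                )
                continue
            pred = np.array([result.labels[d] for d in covered])
            truth = np.array([annot.mapping[d] for d in covered])
            report.external.append({
                "network": name,
                "scheme": annot.scheme,
                "coverage": len(covered),
                "ari": adjusted_rand_index(pred, truth),
                "nmi": normalized_mutual_information(pred, truth),
            })
    return report
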