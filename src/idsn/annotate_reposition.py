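"""Downstream analyses of the fused network.

Covers per-cluster data-type contribution of edges, top-pair pathway
consistency, per-cluster permutation significance, repositioning candidates
(highly similar pairs with conflicting pathway annotations) and a generic
hypergeometric enrichment over user-supplied gene sets.

The edge-attribution rule ranks each network's off-diagonal entries to a
common [0,1] scale before comparison, because the chem, pharm and fused
matrices do not share a scale after fusion; the rule itself is an
interpretation and is documented as such.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom, rankdata

from .core_io import AnnotationTable, CohortError, SimilarityNetwork

logger = logging.getLogger("idsn")

CATEGORIES = ("chemical_structure", "drug_targets", "fusion_value")


@dataclass
class EdgeAttribution:
    """Per within-cluster unordered pair: winning category and the three
    rank-transformed supporting values (chem, pharm, fused)."""

    categories: dict[tuple[str, str], str]
    supports: dict[tuple[str, str], tuple[float, float, float]]
    margin: float


@dataclass
class ContributionReport:
    per_cluster: dict[int, dict[str, float]]       # percentages, sum 100
    per_cluster_edges: dict[int, int]
    global_percent: dict[str, float]
    dominated: dict[int, str]                       # cluster -> category > threshold
    entirely_determined: dict[int, str]             # cluster -> 100% category
    singletons: list[int]
    threshold: float


@dataclass
class PairRow:
    drug_i: str
    drug_j: str
    similarity: float
    pathway_i: str | None = None
    pathway_j: str | None = None
    consistent: bool | None = None


@dataclass
class PairReport:
    rows: list[PairRow]
    consistent_fraction: float | None = None
    dropped_unannotated: int = 0

    def to_tsv(self, path, meta: dict | None = None) -> None:
        with open(path, "w") as fh:
            for key, value in (meta or {}).items():
                fh.write(f"#{key}\t{value}\n")
            if self.consistent_fraction is not None:
                fh.write(f"#consistent_fraction\t{self.consistent_fraction:.10g}\n")
                fh.write(f"#dropped_unannotated\t{self.dropped_unannotated}\n")
            fh.write("drug_i\tdrug_j\tsimilarity\tpathway_i\tpathway_j\tconsistent\n")
            for r in self.rows:
                cons = "" if r.consistent is None else str(int(r.consistent))
                fh.write(
                    f"{r.drug_i}\t{r.drug_j}\t{r.similarity:.17g}\t"
                    f"{r.pathway_i or ''}\t{r.pathway_j or ''}\t{cons}\n"
                )


@dataclass
class EnrichmentRow:
    cluster: int
    gene_set: str
    overlap: int
    cluster_count: int
    set_size: int
    universe_size: int
    p_value: float
    q_value: float = float("nan")


def _rank_transform(matrix: np.ndarray) -> np.ndarray:
    """Rank off-diagonal entries (average ties) and scale to [0,1]."""
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    values = matrix[iu]
    m = values.size
    if m == 0:
        return np.zeros_like(matrix)
    if m == 1:
        scaled = np.array([1.0])
    else:
        scaled = (rankdata(values, method="average") - 1.0) / (m - 1.0)
    out = np.zeros_like(matrix, dtype=float)
    out[iu] = scaled
    out = out + out.T
    return out


def edge_source_attribution(
    fused: SimilarityNetwork,
    chem: SimilarityNetwork,
    pharm: SimilarityNetwork,
    labels: dict[str, int],
    margin: float = 0.05,
) -> EdgeAttribution:
    """Categorize every within-cluster pair by its strongest data source.

    If the fused rank exceeds both single-view ranks by more than ``margin``
    the pair is a ``fusion_value`` edge; otherwise the larger single-view
    rank wins, with exact chem/pharm ties also attributed to fusion.
    """
    if chem.ids != fused.ids or pharm.ids != fused.ids:
        raise CohortError("fused, chem and pharm networks must share id order")
    missing = [d for d in fused.ids if d not in labels]
    if missing:
        raise CohortError(f"drugs missing from labels: {missing}")
    rc = _rank_transform(chem.matrix)
    rp = _rank_transform(pharm.matrix)
    rf = _rank_transform(fused.matrix)
    categories: dict[tuple[str, str], str] = {}
    supports: dict[tuple[str, str], tuple[float, float, float]] = {}
    ids = fused.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if labels[ids[i]] != labels[ids[j]]:
                continue
            c, p, f = rc[i, j], rp[i, j], rf[i, j]
            if f > max(c, p) + margin:
                cat = "fusion_value"
            elif c > p:
                cat = "chemical_structure"
            elif p > c:
                cat = "drug_targets"
            else:
                cat = "fusion_value"
            pair = (ids[i], ids[j])
            categories[pair] = cat
            supports[pair] = (float(c), float(p), float(f))
    return EdgeAttribution(categories=categories, supports=supports, margin=margin)


def cluster_contribution_report(
    attribution: EdgeAttribution,
    labels: dict[str, int],
    dominance_threshold: float = 70.0,
) -> ContributionReport:
    """Percentage of within-cluster edges per category, per cluster and
    globally; clusters with a single dominant category are flagged."""
    clusters = sorted(set(labels.values()))
    counts = {c: {cat: 0 for cat in CATEGORIES} for c in clusters}
    for (di, dj), cat in attribution.categories.items():
        counts[labels[di]][cat] += 1
    per_cluster: dict[int, dict[str, float]] = {}
    edges: dict[int, int] = {}
    dominated: dict[int, str] = {}
    entirely: dict[int, str] = {}
    singletons: list[int] = []
    global_counts = {cat: 0 for cat in CATEGORIES}
    for c in clusters:
        total = sum(counts[c].values())
        edges[c] = total
        if total == 0:
            singletons.append(c)
            continue
        per_cluster[c] = {
            cat: 100.0 * counts[c][cat] / total for cat in CATEGORIES
        }
        for cat in CATEGORIES:
            global_counts[cat] += counts[c][cat]
            if per_cluster[c][cat] > dominance_threshold:
                dominated[c] = cat
            if counts[c][cat] == total:
                entirely[c] = cat
    grand = sum(global_counts.values())
    global_percent = {
        cat: (100.0 * global_counts[cat] / grand if grand else 0.0)
        for cat in CATEGORIES
    }
    return ContributionReport(
        per_cluster=per_cluster,
        per_cluster_edges=edges,
        global_percent=global_percent,
        dominated=dominated,
        entirely_determined=entirely,
        singletons=singletons,
        threshold=dominance_threshold,
    )


def _all_pairs_sorted(net: SimilarityNetwork) -> list[tuple[str, str, float]]:
    ids = net.ids
    pairs = [
        (ids[i], ids[j], float(net.matrix[i, j]))
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return pairs


def top_similar_pairs(net: SimilarityNetwork, n: int) -> PairReport:
    """Top-n unordered off-diagonal pairs by similarity; ties broken by the
    lexicographic id pair so rankings are stable across runs."""
    total = net.n * (net.n - 1) // 2
    if n > total:
        raise CohortError(f"requested {n} pairs but only {total} exist")
    rows = [
        PairRow(drug_i=a, drug_j=b, similarity=s)
        for a, b, s in _all_pairs_sorted(net)[:n]
    ]
    return PairReport(rows=rows)


def pathway_consistency(
    pairs: PairReport, annot: AnnotationTable
) -> tuple[float, PairReport]:
    """Annotate pairs and compute the fraction with identical pathway labels.

    Pairs with an unannotated drug are dropped from the fraction but counted.
    """
    annotated: list[PairRow] = []
    dropped = 0
    for r in pairs.rows:
        pi = annot.mapping.get(r.drug_i)
        pj = annot.mapping.get(r.drug_j)
        if pi is None or pj is None:
            dropped += 1
            continue
        annotated.append(PairRow(
            drug_i=r.drug_i, drug_j=r.drug_j, similarity=r.similarity,
            pathway_i=pi, pathway_j=pj, consistent=(pi == pj),
        ))
    if not annotated:
        raise CohortError("no annotated pairs; cannot compute consistency")
    fraction = sum(r.consistent for r in annotated) / len(annotated)
    return float(fraction), PairReport(
        rows=annotated,
        consistent_fraction=float(fraction),
        dropped_unannotated=dropped,
    )


def cluster_consistency_pvalue(
    labels: dict[str, int],
    net: SimilarityNetwork,
    annot: AnnotationTable,
    top_n: int = 100,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[int, dict]:
    """Permutation significance of each cluster's top-pair pathway consistency.

    Observed statistic: consistent fraction among the cluster's pairs present
    in the global top-n list.  Null: pathway labels permuted across drugs.
    p = (1 + #{null >= observed}) / (1 + n_perm).  Clusters with no top-n
    pairs get p = NaN.
    """
    if n_perm < 100:
        raise CohortError("n_perm must be >= 100")
    top = top_similar_pairs(net, top_n)
    annotated_ids = [d for d in net.ids if d in annot.mapping]
    pos = {d: i for i, d in enumerate(annotated_ids)}
    base_labels = np.array([annot.mapping[d] for d in annotated_ids])
    cluster_pairs: dict[int, list[tuple[int, int]]] = {}
    for r in top.rows:
        if r.drug_i not in pos or r.drug_j not in pos:
            continue
        ci, cj = labels.get(r.drug_i), labels.get(r.drug_j)
        if ci is None or cj is None or ci != cj:
            continue
        cluster_pairs.setdefault(ci, []).append((pos[r.drug_i], pos[r.drug_j]))
    rng = np.random.default_rng(seed)
    out: dict[int, dict] = {}
    clusters = sorted(set(labels.values()))
    pair_arrays = {
        c: (np.array([p[0] for p in ps]), np.array([p[1] for p in ps]))
        for c, ps in cluster_pairs.items()
    }
    observed = {
        c: float(np.mean(base_labels[ii] == base_labels[jj]))
        for c, (ii, jj) in pair_arrays.items()
    }
    null_ge = {c: 0 for c in pair_arrays}
    for _ in range(n_perm):
        perm = base_labels[rng.permutation(base_labels.size)]
        for c, (ii, jj) in pair_arrays.items():
            stat = float(np.mean(perm[ii] == perm[jj]))
            if stat >= observed[c] - 1e-12:
                null_ge[c] += 1
    for c in clusters:
        if c not in pair_arrays:
            out[c] = {"p": float("nan"), "neg_log10_p": float("nan"),
                      "n_pairs": 0, "observed": float("nan")}
            continue
        p = (1 + null_ge[c]) / (1 + n_perm)
        out[c] = {
            "p": float(p),
            "neg_log10_p": float(-math.log10(p)),
            "n_pairs": len(cluster_pairs[c]),
            "observed": observed[c],
        }
    return out


def repositioning_candidates(
    net: SimilarityNetwork,
    annot: AnnotationTable,
    sim_threshold: float = 0.7,
) -> PairReport:
    """Annotated pairs with similarity strictly above the threshold whose
    pathway labels differ — each row suggests the partner's pathway as the
    drug's potential pathway."""
    if not (0.0 < sim_threshold < 1.0):
        raise CohortError("threshold must be in (0,1)")
    rows: list[PairRow] = []
    for a, b, s in _all_pairs_sorted(net):
        if s <= sim_threshold:
            break
        pa, pb = annot.mapping.get(a), annot.mapping.get(b)
        if pa is None or pb is None or pa == pb:
            continue
        rows.append(PairRow(
            drug_i=a, drug_j=b, similarity=s,
            pathway_i=pa, pathway_j=pb, consistent=False,
        ))
    return PairReport(rows=rows)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeometric_enrichment(
    cluster_targets: dict[int, set[str]],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric over-representation of each gene set in each
    cluster's target set, BH-adjusted across all rows, sorted by q then p."""
    if not universe:
        raise CohortError("empty universe")
    for c, targets in cluster_targets.items():
        extra = targets - universe
        if extra:
            raise CohortError(f"cluster {c} targets outside universe: {sorted(extra)}")
    N = len(universe)
    rows: list[EnrichmentRow] = []
    for c in sorted(cluster_targets):
        draw = cluster_targets[c]
        for name in sorted(gene_sets):
            gset = gene_sets[name] & universe
            overlap = len(draw & gset)
            # upper tail including the observed overlap
            p = float(hypergeom.sf(overlap - 1, N, len(gset), len(draw)))
            rows.append(EnrichmentRow(
                cluster=c, gene_set=name, overlap=overlap,
                cluster_count=len(draw), set_size=len(gset),
                universe_size=N, p_value=min(p, 1.0),
            ))
    if rows:
        qs = benjamini_hochberg(np.array([r.p_value for r in rows]))
        for r, q in zip(rows, qs):
            r.q_value = float(q)
        rows.sort(key=lambda r: (r.q_value, r.p_value, r.cluster, r.gene_set))
    return rows
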