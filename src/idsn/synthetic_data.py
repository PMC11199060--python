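"""Synthetic drug cohorts with planted cluster structure in both data views.

Each cluster gets a prototype fingerprint and a prototype target sequence;
drugs inherit noisy copies (independent bit flips / per-site substitutions)
and a pathway label that is contaminated at a configurable rate.  A single
seed drives four named substreams (prototypes, chem noise, pharm noise,
label contamination) so changing one rate never shifts the other draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import AMINO_ACIDS, CohortError, DrugProfile, SimilarityNetwork
from .dsn_build import AlignmentScoring, build_chem_dsn, build_pharm_dsn

logger = logging.getLogger("idsn")


@dataclass
class SyntheticSpec:
    n_clusters: int = 4
    drugs_per_cluster: int | list[int] = 15
    fingerprint_length: int = 1024
    prototype_density: float = 0.1
    p_chem: float = 0.02
    target_length: int = 60
    p_pharm: float = 0.02
    contamination: float = 0.0
    targets_per_drug: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise CohortError("n_clusters must be >= 2")
        for rate in (self.p_chem, self.p_pharm, self.contamination):
            if not (0.0 <= rate < 1.0):
                raise CohortError(f"rate {rate} must be in [0,1)")
        if not (0.0 < self.prototype_density <= 1.0):
            raise CohortError("prototype_density must be in (0,1]")
        for length in (self.fingerprint_length, self.target_length,
                       self.targets_per_drug):
            if int(length) <= 0:
                raise CohortError("lengths/counts must be positive")
        sizes = self.cluster_sizes()
        if len(sizes) != self.n_clusters or any(s <= 0 for s in sizes):
            raise CohortError("drugs_per_cluster must give one positive size per cluster")

    def cluster_sizes(self) -> list[int]:
        if isinstance(self.drugs_per_cluster, int):
            return [self.drugs_per_cluster] * self.n_clusters
        return list(self.drugs_per_cluster)


@dataclass
class GroundTruth:
    cluster_of: dict[str, int]
    pathway_of_cluster: dict[int, str]
    label_of: dict[str, str] = field(default_factory=dict)  # possibly contaminated

    def label_array(self, ids: list[str]) -> np.ndarray:
        return np.array([self.cluster_of[d] for d in ids], dtype=int)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("prototypes", "chem", "pharm", "labels")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def generate_cohort(
    spec: SyntheticSpec,
    chem_merge: dict[int, int] | None = None,
    pharm_merge: dict[int, int] | None = None,
) -> tuple[list[DrugProfile], GroundTruth]:
    """Build a cohort of noisy copies of per-cluster prototypes.

    ``chem_merge`` / ``pharm_merge`` map a cluster onto another cluster whose
    prototype it reuses in that view — this is how the two-view benchmark
    plants complementary degradation.
    """
    rngs = _substreams(spec.seed)
    sizes = spec.cluster_sizes()
    L = spec.fingerprint_length
    proto_rng = rngs["prototypes"]
    fp_protos = []
    seq_protos = []
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    for _ in range(spec.n_clusters):
        fp = (proto_rng.random(L) < spec.prototype_density).astype(np.uint8)
        if not fp.any():
            fp[proto_rng.integers(L)] = 1
        fp_protos.append(fp)
        seq = aa[proto_rng.integers(0, len(aa), size=spec.target_length)]
        seq_protos.append(seq)
    chem_merge = chem_merge or {}
    pharm_merge = pharm_merge or {}

    pathway_labels = {c: f"PW{c:02d}" for c in range(spec.n_clusters)}
    all_labels = [pathway_labels[c] for c in range(spec.n_clusters)]

    profiles: list[DrugProfile] = []
    cluster_of: dict[str, int] = {}
    label_of: dict[str, str] = {}
    chem_rng, pharm_rng, label_rng = rngs["chem"], rngs["pharm"], rngs["labels"]
    idx = 0
    for c, size in enumerate(sizes):
        fp_proto = fp_protos[chem_merge.get(c, c)]
        seq_proto = seq_protos[pharm_merge.get(c, c)]
        for _ in range(size):
            did = f"d{idx:03d}"
            idx += 1
            flips = chem_rng.random(L) < spec.p_chem
            bits = np.where(flips, 1 - fp_proto, fp_proto).astype(np.uint8)
            if not bits.any():
                bits[int(chem_rng.integers(L))] = 1
            targets = []
            for t in range(spec.targets_per_drug):
                mutate = pharm_rng.random(spec.target_length) < spec.p_pharm
                subs = aa[pharm_rng.integers(0, len(aa), size=spec.target_length)]
                # resample until different from the original at mutated sites
                seq = seq_proto.copy()
                site_idx = np.flatnonzero(mutate)
                for s in site_idx:
                    new = subs[s]
                    while new == seq_proto[s]:
                        new = aa[int(pharm_rng.integers(len(aa)))]
                    seq[s] = new
                targets.append((f"G{c:02d}_{t}", seq.tobytes().decode()))
            label = pathway_labels[c]
            if label_rng.random() < spec.contamination:
                label = all_labels[int(label_rng.integers(len(all_labels)))]
            profiles.append(DrugProfile(
                drug_id=did,
                structure="".join(map(str, bits)),
                fingerprint=bits,
                targets=targets,
                pathway=label,
            ))
            cluster_of[did] = c
            label_of[did] = label
    truth = GroundTruth(
        cluster_of=cluster_of,
        pathway_of_cluster=pathway_labels,
        label_of=label_of,
    )
    return profiles, truth


def planted_two_view_benchmark(
    spec: SyntheticSpec,
    degrade: str = "both-complementary",
    scoring: AlignmentScoring | None = None,
    aggregator: str = "max",
    floor: float = 1e-6,
) -> tuple[SimilarityNetwork, SimilarityNetwork, GroundTruth]:
    """Chem- and pharm-DSNs over one cohort with a chosen view degraded.

    ``chem`` / ``pharm`` crank that view's noise to near-uninformative;
    ``both-complementary`` merges the chem prototypes of clusters 0 and 1 and
    the sequence prototypes of clusters 2 and 3, so each single view confuses
    one cluster pair and only their fusion can resolve all clusters.

    ``floor`` lifts exact-zero off-diagonal similarities (clamped alignment
    scores between unrelated families produce many) so the single views stay
    connected and can be spectrally clustered for the comparison.
    """
    if degrade not in ("chem", "pharm", "both-complementary"):
        raise CohortError(f"unknown degradation {degrade!r}")
    chem_merge = pharm_merge = None
    if degrade == "chem":
        spec = SyntheticSpec(**{**_spec_dict(spec), "p_chem": 0.45})
    elif degrade == "pharm":
        spec = SyntheticSpec(**{**_spec_dict(spec), "p_pharm": 0.90})
    else:
        if spec.n_clusters < 4:
            raise CohortError("both-complementary needs >= 4 clusters")
        chem_merge = {1: 0}
        pharm_merge = {3: 2}
    profiles, truth = generate_cohort(
        spec, chem_merge=chem_merge, pharm_merge=pharm_merge
    )
    chem = build_chem_dsn(profiles)
    pharm = build_pharm_dsn(profiles, scoring=scoring, aggregator=aggregator)
    if floor > 0:
        for net in (chem, pharm):
            M = np.maximum(net.matrix, floor)
            np.fill_diagonal(M, 1.0)
            net.matrix = M
    return chem, pharm, truth


def _spec_dict(spec: SyntheticSpec) -> dict:
    return {
        "n_clusters": spec.n_clusters,
        "drugs_per_cluster": spec.drugs_per_cluster,
        "fingerprint_length": spec.fingerprint_length,
        "prototype_density": spec.prototype_density,
        "p_chem": spec.p_chem,
        "target_length": spec.target_length,
        "p_pharm": spec.p_pharm,
        "contamination": spec.contamination,
        "targets_per_drug": spec.targets_per_drug,
        "seed": spec.seed,
    }


def make_planted_network(
    n_clusters: int,
    per_cluster: int,
    within: float = 0.9,
    between: float = 0.1,
    noise: float = 0.01,
    seed: int = 0,
    source: str = "fused",
) -> tuple[SimilarityNetwork, GroundTruth]:
    """Direct block similarity matrix (no sequences/fingerprints involved) —
    handy for exercising clustering and consistency statistics in isolation."""
    rng = np.random.default_rng(seed)
    n = n_clusters * per_cluster
    labels = np.repeat(np.arange(n_clusters), per_cluster)
    M = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if noise > 0:
        eps = rng.normal(0.0, noise, size=(n, n))
        M = M + (eps + eps.T) / 2.0
    M = np.clip(M, 0.0, 1.0)
    np.fill_diagonal(M, 1.0)
    ids = [f"d{i:03d}" for i in range(n)]
    truth = GroundTruth(
        cluster_of={d: int(c) for d, c in zip(ids, labels)},
        pathway_of_cluster={c: f"PW{c:02d}" for c in range(n_clusters)},
        label_of={d: f"PW{c:02d}" for d, c in zip(ids, labels)},
    )
    return SimilarityNetwork(ids=ids, matrix=M, source=source), truth


def write_cohort(
    profiles: list[DrugProfile],
    truth: GroundTruth,
    out_dir: str | Path,
    force: bool = False,
) -> dict[str, Path]:
    """Emit drug table CSV, targets FASTA, pathway CSV and truth CSV in the
    exact formats the readers accept."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise CohortError(f"{out_dir} is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "drug_table": out_dir / "drug_table.csv",
        "targets": out_dir / "targets.fasta",
        "pathway": out_dir / "pathway.csv",
        "truth": out_dir / "truth.csv",
    }
    with paths["drug_table"].open("w") as fh:
        fh.write("drug_id,structure,pathway\n")
        for p in profiles:
            fh.write(f"{p.drug_id},{p.structure},{p.pathway or ''}\n")
    with paths["targets"].open("w") as fh:
        for p in profiles:
            for tid, seq in p.targets:
                fh.write(f">{p.drug_id}|{tid}\n{seq}\n")
    with paths["pathway"].open("w") as fh:
        fh.write("drug_id,pathway\n")
        for p in profiles:
            if p.pathway is not None:
                fh.write(f"{p.drug_id},{p.pathway}\n")
    with paths["truth"].open("w") as fh:
        fh.write("drug_id,cluster\n")
        for p in profiles:
            fh.write(f"{p.drug_id},{truth.cluster_of[p.drug_id]}\n")
    return paths
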