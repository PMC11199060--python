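"""Domain types, file readers/writers and configuration shared by every stage.

All tabular formats are plain text (CSV/TSV), matrices are TSV with a
``#``-prefixed metadata header, and target sequences travel as FASTA with
``drug_id|target_id`` headers.  Every writer stamps the pipeline config hash
and seed so outputs are traceable and byte-reproducible.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("idsn")

#: 20 standard amino acids plus the ambiguity code X.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ALPHABET = frozenset(AMINO_ACIDS + "X")

SOURCES = ("chem", "pharm", "fused")
SCALES = ("similarity", "affinity")

SYMMETRY_TOL = 1e-10


class CohortError(ValueError):
    """Raised on malformed cohort inputs (duplicate ids, bad columns, ...)."""


@dataclass
class DrugProfile:
    """One drug of a cohort.

    ``structure`` holds either a SMILES string or a fingerprint bitstring;
    ``fingerprint`` is filled in by :mod:`idsn.dsn_build`.
    """

    drug_id: str
    structure: str
    fingerprint: np.ndarray | None = None
    targets: list[tuple[str, str]] = field(default_factory=list)
    pathway: str | None = None
    extra_annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise CohortError("drug_id must be non-empty")


@dataclass
class SimilarityNetwork:
    """Symmetric non-negative drug x drug matrix with an ordered id index."""

    ids: list[str]
    matrix: np.ndarray
    source: str
    scale: str = "similarity"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise CohortError(f"duplicate ids in network: {dupes}")
        if self.matrix.shape != (n, n):
            raise CohortError(
                f"matrix shape {self.matrix.shape} does not match {n} ids"
            )
        if self.source not in SOURCES:
            raise CohortError(f"unknown source {self.source!r}")
        if self.scale not in SCALES:
            raise CohortError(f"unknown scale {self.scale!r}")
        asym = float(np.max(np.abs(self.matrix - self.matrix.T))) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise CohortError(f"matrix asymmetric: max |Mij-Mji| = {asym:g}")
        if n and float(self.matrix.min()) < 0:
            raise CohortError(f"negative entry {self.matrix.min():g} in matrix")
        if self.scale == "similarity" and n and float(self.matrix.max()) > 1 + 1e-9:
            raise CohortError(
                f"similarity-scale entry {self.matrix.max():g} exceeds 1"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.ids)}

    def subset(self, ids: Iterable[str]) -> "SimilarityNetwork":
        """Restrict to ``ids`` (kept in the given order)."""
        ids = list(ids)
        pos = self.index_of()
        missing = [i for i in ids if i not in pos]
        if missing:
            raise CohortError(f"ids not in network: {missing}")
        idx = np.array([pos[i] for i in ids], dtype=int)
        return SimilarityNetwork(
            ids=ids, matrix=self.matrix[np.ix_(idx, idx)],
            source=self.source, scale=self.scale,
        )


@dataclass
class AnnotationTable:
    """A single annotation scheme: drug_id -> category label."""

    scheme: str
    mapping: dict[str, str]

    @property
    def categories(self) -> set[str]:
        return set(self.mapping.values())


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; hashed into every output header."""

    fingerprint_length: int = 2048
    fingerprint_radius: int = 2
    chem_metric: str = "cosine"  # cosine | tanimoto
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5
    alignment_mode: str = "global"
    aggregator: str = "max"  # max | mean
    snf_k: int = 20
    snf_mu: float = 0.5
    snf_iterations: int = 20
    snf_eps_reg: float = 1e-8
    n_clusters: int = 16
    seed: int = 0
    top_n_pairs: int = 100
    similarity_threshold: float = 0.7
    n_permutations: int = 999

    def __post_init__(self) -> None:
        for name in ("fingerprint_length", "snf_k", "snf_iterations",
                     "n_clusters", "top_n_pairs", "n_permutations"):
            if int(getattr(self, name)) <= 0:
                raise CohortError(f"{name} must be a positive integer")
        if not (0.0 < self.similarity_threshold < 1.0):
            raise CohortError("similarity_threshold must be in (0,1)")
        if self.snf_mu <= 0:
            raise CohortError("snf_mu must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_drug_table(path: str | Path) -> list[DrugProfile]:
    """Read a CSV/TSV drug table into :class:`DrugProfile` rows.

    Requires ``drug_id`` and ``structure`` columns; an optional ``pathway``
    column fills the pathway label (blank cells leave it unset).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise CohortError(f"{path}: empty drug table")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        cols = reader.fieldnames or []
        for required in ("drug_id", "structure"):
            if required not in cols:
                raise CohortError(f"{path}: missing required column {required!r}")
        profiles: list[DrugProfile] = []
        seen: set[str] = set()
        for row in reader:
            did = (row["drug_id"] or "").strip()
            if not did:
                raise CohortError(f"{path}: blank drug_id")
            if did in seen:
                raise CohortError(f"{path}: duplicate drug_id {did!r}")
            seen.add(did)
            pathway = (row.get("pathway") or "").strip() or None
            profiles.append(DrugProfile(
                drug_id=did, structure=(row["structure"] or "").strip(),
                pathway=pathway,
            ))
    return profiles


def read_target_fasta(
    path: str | Path, profiles: list[DrugProfile]
) -> list[DrugProfile]:
    """Attach target sequences from a ``drug_id|target_id`` FASTA to profiles.

    Drugs absent from the FASTA keep empty target lists; their count is
    logged.  Returns the same profile list, updated in place.
    """
    path = Path(path)
    by_id = {p.drug_id: p for p in profiles}
    if len(by_id) != len(profiles):
        raise CohortError("duplicate drug_id among profiles")
    for lineno, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = record.id
        if "|" not in header:
            raise CohortError(
                f"{path}: record {lineno}: header {header!r} does not match "
                "'drug_id|target_id'"
            )
        drug_id, target_id = header.split("|", 1)
        if not drug_id or not target_id:
            raise CohortError(
                f"{path}: record {lineno}: header {header!r} does not match "
                "'drug_id|target_id'"
            )
        if drug_id not in by_id:
            raise CohortError(
                f"{path}: record {lineno}: unknown drug_id {drug_id!r}"
            )
        seq = str(record.seq).upper()
        if not seq:
            raise CohortError(f"{path}: record {lineno}: empty sequence")
        bad = set(seq) - AMINO_ALPHABET
        if bad:
            raise CohortError(
                f"{path}: record {lineno}: invalid residues {sorted(bad)}"
            )
        by_id[drug_id].targets.append((target_id, seq))
    missing = [p.drug_id for p in profiles if not p.targets]
    if missing:
        logger.warning("%d drugs have no targets: %s", len(missing), missing)
    return profiles


def drugs_without_targets(profiles: list[DrugProfile]) -> list[str]:
    return [p.drug_id for p in profiles if not p.targets]


def read_annotation_table(path: str | Path, scheme: str) -> AnnotationTable:
    """Read a two-column CSV/TSV (drug_id, label) annotation table."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            return AnnotationTable(scheme=scheme, mapping={})
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        if len(header) < 2:
            raise CohortError(f"{path}: expected two columns")
        for row in reader:
            if not row or not row[0].strip():
                continue
            did, label = row[0].strip(), row[1].strip()
            if did in mapping:
                raise CohortError(f"{path}: duplicate drug_id {did!r}")
            mapping[did] = label
    return AnnotationTable(scheme=scheme, mapping=mapping)


def write_network(
    net: SimilarityNetwork,
    path: str | Path,
    config_hash: str = "",
    seed: int | None = None,
    extra_meta: dict[str, str] | None = None,
) -> None:
    """Write a network as TSV: ``#key<TAB>value`` metadata, id header, rows.

    Floats use ``%.17g`` so a round-trip is exact to double precision.
    """
    net.validate()
    path = Path(path)
    meta = {"source": net.source, "scale": net.scale}
    if config_hash:
        meta["config_hash"] = config_hash
    if seed is not None:
        meta["seed"] = str(seed)
    if extra_meta:
        meta.update(extra_meta)
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"#{key}\t{value}\n")
        fh.write("id\t" + "\t".join(net.ids) + "\n")
        for i, did in enumerate(net.ids):
            row = "\t".join(f"{v:.17g}" for v in net.matrix[i])
            fh.write(f"{did}\t{row}\n")


def read_network(path: str | Path) -> SimilarityNetwork:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    meta: dict[str, str] = {}
    ids: list[str] = []
    rows: list[list[float]] = []
    row_ids: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key] = value
                continue
            cells = line.split("\t")
            if not ids:
                if cells[0] != "id":
                    raise CohortError(f"{path}: expected 'id' header row")
                ids = cells[1:]
                continue
            row_ids.append(cells[0])
            rows.append([float(c) for c in cells[1:]])
    for required in ("source", "scale"):
        if required not in meta:
            raise CohortError(f"{path}: metadata header missing {required!r}")
    if row_ids != ids:
        raise CohortError(f"{path}: row ids do not match column ids")
    matrix = np.array(rows, dtype=float)
    if matrix.size:
        asym = float(np.max(np.abs(matrix - matrix.T)))
        if asym > SYMMETRY_TOL:
            raise CohortError(f"{path}: asymmetric matrix, max |Mij-Mji| = {asym:g}")
    return SimilarityNetwork(
        ids=ids, matrix=matrix, source=meta["source"], scale=meta["scale"]
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <TAB> description <TAB> genes..."""
    sets: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 3 or not cells[0]:
                continue
            sets[cells[0]] = {g for g in cells[2:] if g}
    return sets


def write_labels(
    labels: dict[str, int],
    path: str | Path,
    config_hash: str = "",
    seed: int | None = None,
) -> None:
    with Path(path).open("w") as fh:
        if config_hash:
            fh.write(f"#config_hash\t{config_hash}\n")
        if seed is not None:
            fh.write(f"#seed\t{seed}\n")
        fh.write("drug_id\tcluster\n")
        for did, lab in labels.items():
            fh.write(f"{did}\t{lab}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    labels: dict[str, int] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("drug_id\t"):
                continue
            did, lab = line.split("\t")
            labels[did] = int(lab)
    return labels
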