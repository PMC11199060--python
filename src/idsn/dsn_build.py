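"""Single-property drug similarity networks.

chem-DSN: hashed circular-substructure fingerprints compared in a vector
space (cosine by default, Tanimoto selectable).  pharm-DSN: pairwise global
alignment of target protein sequences, normalized by the geometric mean of
the self-alignment scores and clamped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import CohortError, DrugProfile, SimilarityNetwork

logger = logging.getLogger("idsn")


@dataclass
class Fingerprint:
    bits: np.ndarray  # uint8 vector of 0/1
    length: int
    radius: int

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (self.length,):
            raise CohortError(
                f"fingerprint has {self.bits.size} bits, expected {self.length}"
            )
        if not self.bits.any():
            raise CohortError("fingerprint has no set bits")


@dataclass
class AlignmentScoring:
    """Pairwise alignment parameters for the pharmacological view."""

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5
    mode: str = "global"

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise CohortError("gap penalties must be strictly negative")
        if self.mode not in ("global", "local"):
            raise CohortError(f"unknown alignment mode {self.mode!r}")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(
            self.substitution_matrix
        )
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        aligner.mode = self.mode
        return aligner


def _is_bitstring(structure: str) -> bool:
    return len(structure) > 0 and set(structure) <= {"0", "1"}


def structural_fingerprint(
    structure: str, length: int = 2048, radius: int = 2, drug_id: str = "?"
) -> Fingerprint:
    """Fingerprint a structure: bitstrings pass through, SMILES are hashed
    into circular substructure bits (Morgan) of the requested radius."""
    if _is_bitstring(structure):
        if len(structure) != length:
            raise CohortError(
                f"drug {drug_id}: bitstring length {len(structure)} != {length}"
            )
        bits = np.frombuffer(structure.encode(), dtype=np.uint8) - ord("0")
        return Fingerprint(bits=bits.copy(), length=length, radius=radius)
    # SMILES path; import kept local so bitstring cohorts work without rdkit.
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise CohortError(f"drug {drug_id}: unparseable SMILES {structure!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=length)
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(length, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return Fingerprint(bits=bits, length=length, radius=radius)


def fingerprint_profiles(
    profiles: list[DrugProfile], length: int = 2048, radius: int = 2
) -> list[DrugProfile]:
    """Fill ``profile.fingerprint`` for every profile (in place)."""
    for p in profiles:
        fp = structural_fingerprint(p.structure, length, radius, drug_id=p.drug_id)
        p.fingerprint = fp.bits
    return profiles


def cosine_similarity(u: np.ndarray, v: np.ndarray, drug_ids=("?", "?")) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise CohortError(f"vector length mismatch: {u.size} vs {v.size}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0:
        raise CohortError(f"drug {drug_ids[0]}: zero vector")
    if nv == 0:
        raise CohortError(f"drug {drug_ids[1]}: zero vector")
    return float(np.dot(u, v) / (nu * nv))


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    if a.length != b.length:
        raise CohortError(f"fingerprint length mismatch: {a.length} vs {b.length}")
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    return inter / union if union else 0.0


def build_chem_dsn(
    profiles: list[DrugProfile], metric: str = "cosine"
) -> SimilarityNetwork:
    """Pairwise fingerprint similarity matrix; diagonal 1, ids in profile order."""
    if metric not in ("cosine", "tanimoto"):
        raise CohortError(f"unknown chem metric {metric!r}")
    ids = [p.drug_id for p in profiles]
    for p in profiles:
        if p.fingerprint is None:
            raise CohortError(f"drug {p.drug_id}: fingerprint not set")
        if not np.any(p.fingerprint):
            raise CohortError(f"drug {p.drug_id}: zero vector")
    X = np.array([p.fingerprint for p in profiles], dtype=float)
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        M = (X / norms[:, None]) @ (X / norms[:, None]).T
    else:
        inter = X @ X.T
        pop = X.sum(axis=1)
        union = pop[:, None] + pop[None, :] - inter
        M = np.divide(inter, union, out=np.zeros_like(inter), where=union > 0)
    M = np.clip((M + M.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(M, 1.0)
    return SimilarityNetwork(ids=ids, matrix=M, source="chem")


def alignment_score(a: str, b: str, scoring: AlignmentScoring) -> float:
    return float(scoring.make_aligner().score(a, b))


def normalized_alignment_similarity(
    a: str, b: str, scoring: AlignmentScoring, _cache: dict | None = None
) -> float:
    """S(a,b) / sqrt(S(a,a) * S(b,b)), clamped to [0, 1].

    ``_cache`` (optional dict) memoizes raw scores keyed by sequence pair,
    which matters when cohorts share prototype sequences.
    """
    if not a or not b:
        raise CohortError("empty sequence")

    def score(x: str, y: str) -> float:
        if _cache is None:
            return alignment_score(x, y, scoring)
        key = (x, y) if x <= y else (y, x)
        if key not in _cache:
            _cache[key] = alignment_score(key[0], key[1], scoring)
        return _cache[key]

    saa, sbb = score(a, a), score(b, b)
    if saa <= 0 or sbb <= 0:
        raise CohortError("non-positive self-alignment score; degenerate scoring")
    value = score(a, b) / np.sqrt(saa * sbb)
    return float(min(max(value, 0.0), 1.0))


def drug_pair_target_similarity(
    a: DrugProfile,
    b: DrugProfile,
    scoring: AlignmentScoring,
    aggregator: str = "max",
    _cache: dict | None = None,
) -> float:
    """Aggregate normalized alignment similarity over all cross target pairs."""
    if aggregator not in ("max", "mean"):
        raise CohortError(f"unknown aggregator {aggregator!r}")
    if not a.targets:
        raise CohortError(f"drug {a.drug_id}: empty target list")
    if not b.targets:
        raise CohortError(f"drug {b.drug_id}: empty target list")
    sims = [
        normalized_alignment_similarity(sa, sb, scoring, _cache=_cache)
        for _, sa in a.targets
        for _, sb in b.targets
    ]
    return float(max(sims) if aggregator == "max" else np.mean(sims))


def build_pharm_dsn(
    profiles: list[DrugProfile],
    scoring: AlignmentScoring | None = None,
    aggregator: str = "max",
) -> SimilarityNetwork:
    """Pairwise target-sequence similarity matrix over drugs with >=1 target."""
    scoring = scoring or AlignmentScoring()
    missing = [p.drug_id for p in profiles if not p.targets]
    if missing:
        raise CohortError(
            f"drugs without targets must be excluded upstream: {missing}"
        )
    ids = [p.drug_id for p in profiles]
    n = len(profiles)
    cache: dict = {}
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = drug_pair_target_similarity(
                profiles[i], profiles[j], scoring, aggregator, _cache=cache
            )
            M[i, j] = M[j, i] = s
    return SimilarityNetwork(ids=ids, matrix=M, source="pharm")
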