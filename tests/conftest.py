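import numpy as np
import pytest

from idsn.core_io import SimilarityNetwork
from idsn.synthetic_data import GroundTruth, SyntheticSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_symmetric_similarity(n, rng, source="fused"):
    M = rng.random((n, n))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    ids = [f"d{i:03d}" for i in range(n)]
    return SimilarityNetwork(ids=ids, matrix=M, source=source)


@pytest.fixture
def small_cohort():
    spec = SyntheticSpec(
        n_clusters=3, drugs_per_cluster=5, fingerprint_length=256,
        target_length=40, seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture
def drug_table_csv(tmp_path):
    path = tmp_path / "drugs.csv"
    path.write_text(
        "drug_id,structure,pathway\n"
        "d1,CCO,PI3K\n"
        "d2,c1ccccc1,\n"
        "d3,CC(=O)O,RTK\n"
    )
    return path


@pytest.fixture
def target_fasta(tmp_path):
    path = tmp_path / "targets.fasta"
    path.write_text(
        ">d1|EGFR\nMKKFFDSRREQGGSGLGSGSS\n"
        ">d1|ERBB2\nMELAALCRWGLLLALLPPGAA\n"
        ">d2|BRAF\nMAALSGGGGGGAEPGQALFNG\n"
    )
    return path
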