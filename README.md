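# idsn

Multiscale drug-similarity network toolkit: build chemical and
pharmacological drug similarity networks (DSNs), fuse them into an
integrated network (iDSN) with similarity network fusion, cluster and
evaluate the result, attribute fused edges to their source data type, and
derive drug-repositioning candidates from pathway-inconsistent highly
similar drug pairs.

## What it does

1. **chem-DSN** — hashed circular-substructure fingerprints (radius 2,
   2048 bits by default; raw bitstrings pass through) compared with cosine
   similarity (Tanimoto selectable).
2. **pharm-DSN** — pairwise global alignment of target protein sequences
   (BLOSUM62, gap open −10 / extend −0.5), normalized by the geometric mean
   of the self-alignment scores and clamped to [0, 1]; multi-target drugs
   aggregate cross-pair similarities with `max` (or `mean`).
3. **Fusion** — canonical SNF cross-diffusion (scaled-exponential affinity
   kernel, K-NN local kernels, iterative diffusion). Defaults K=20, mu=0.5,
   T=20; the upstream description does not fix these, so all are
   config-exposed.
4. **Clustering & evaluation** — spectral clustering on the symmetric
   normalized Laplacian with deterministic eigenvector signs and
   size-ordered labels; eigengap guidance for k; ARI, NMI, silhouette,
   Davies–Bouldin and Calinski–Harabasz reports against arbitrary
   annotation schemes.
5. **Downstream** — per-cluster edge attribution
   (chemical_structure / drug_targets / fusion_value, via rank-transformed
   similarities), top-pair pathway consistency, per-cluster permutation
   p-values, repositioning candidates (similarity strictly > 0.7 with
   conflicting pathways), and hypergeometric enrichment against GMT gene
   sets with Benjamini–Hochberg correction.
6. **Synthetic cohorts** — planted-cluster drug cohorts (correlated
   fingerprints, mutated target sequences, contaminated pathway labels) so
   every stage is testable offline, including a complementary two-view
   benchmark where only fusion can recover all clusters.

## CLI

Every stage reads/writes plain-text formats (CSV/TSV tables, FASTA with
`drug_id|target_id` headers, TSV matrices with `#key<TAB>value` metadata):

```sh
idsn simulate --clusters 4 --per-cluster 15 --seed 7 --out cohort/
idsn build-chem cohort/drug_table.csv --metric cosine --out chem.tsv
idsn build-pharm cohort/drug_table.csv cohort/targets.fasta --out pharm.tsv
idsn fuse chem.tsv pharm.tsv --k 20 --mu 0.5 --iterations 20 --out idsn.tsv
idsn cluster idsn.tsv --k 16 --seed 7 --out labels.tsv
idsn evaluate --networks chem.tsv --networks pharm.tsv --networks idsn.tsv \
    --annotations cohort/pathway.csv --k 16 --out report.tsv
idsn contribute idsn.tsv chem.tsv pharm.tsv labels.tsv --out contrib.tsv
idsn pairs idsn.tsv --top 100 --annot cohort/pathway.csv --out pairs.tsv
idsn candidates idsn.tsv cohort/pathway.csv --threshold 0.7 --out cand.tsv
idsn enrich labels.tsv cohort/targets.fasta cohort/drug_table.csv \
    --gmt sets.gmt --out enrich.tsv
```

Outputs are stamped with a config hash and seed; reruns with identical
inputs and options are byte-identical.

## Notes on interpretation

The fused-edge attribution rule, the permutation test behind per-cluster
consistency p-values, and the SNF kernel constants are interpretations:
the method description this package operationalizes names the components
but not these details. All of them are exposed as configuration and
documented in the relevant docstrings.
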