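# radrobust

Cross-software radiomic feature robustness analysis.

Radiomic feature tables exported by two extraction platforms for the same
lesions rarely agree perfectly. `radrobust` implements a multi-stage
workflow that identifies the features that survive both intra-software and
cross-software scrutiny:

1. **Reliability screen** — ICC(A,1) (two-way model, single measurement,
   absolute agreement) on repeated segmentations of the same lesions;
   features with ICC ≥ 0.75 are retained.
2. **Distance matrices** — feature–feature dissimilarities under five
   metrics: Pearson/Spearman correlation distance `sqrt(2·(1−r))`,
   Euclidean, Manhattan and cosine.
3. **Hierarchical clustering** — agglomerative clustering under ward.D2,
   average, complete, single and centroid linkage; the number of clusters is
   chosen by majority rule over internal validity indices (Silhouette, Dunn,
   Calinski–Harabasz) with an early-stop on collapsing support.
4. **Stability gate** — both platforms are clustered independently for every
   (metric, linkage) configuration and compared by the Adjusted Rand Index;
   configurations with ARI ≥ 0.8 are "stable".
5. **Composite Index** — per feature,
   `CI = z_corr − z_KS − z_MFR` (robust z-scores of the inter-platform
   Pearson correlation, the two-sample Kolmogorov–Smirnov statistic and the
   stabilized log mean-ratio). Each cluster's highest-CI feature is its
   "winner"; near-winners sit within a CI tolerance; quality-control filters
   remove weakly correlated and redundant selections; winner frequencies are
   aggregated across all stable solutions.

A seeded synthetic-data generator produces paired platform tables with
block-correlated features, per-feature scale bias, targeted corruptions and
repeated measurements with controlled reliability, so the entire workflow is
testable with known ground truth.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the desk-scale acceptance criteria
(oracle equivalence for ICC / distances / ARI / merge sequences, copy-limit
behaviour, parameter recovery on 50 seeded replicates, and manifest
determinism).

## CLI

```bash
# synthetic paired tables + repeated measures + ground truth
radrobust simulate --seed 1 --out sim/

# per-feature ICC(A,1) from long-format repeated measures
radrobust icc --input sim/repeated_a.csv --out icc.csv

# cluster one table's features (consensus k unless --k is given)
radrobust cluster --input sim/platform_a.csv --metric pearson \
    --linkage average --out partition.csv

# metric x linkage ARI grid between two platforms
radrobust stability --a sim/platform_a.csv --b sim/platform_b.csv --out grid.csv

# Composite Index winners for one configuration
radrobust select --a sim/platform_a.csv --b sim/platform_b.csv \
    --metric pearson --linkage average --k 6 --out winners.csv

# full pipeline from a YAML config
radrobust run --config config.yaml --out run/
```

Minimal `config.yaml`:

```yaml
simulate: {n_lesions: 100, n_features: 60, n_blocks: 6}
seed: 7
# or: platform_a: a.csv / platform_b: b.csv / repeated_a: rep_a.csv ...
```

Every run directory contains the aligned tables, ICC tables, the stability
grid CSV, per-solution robustness/winner CSVs, aggregated winner
frequencies, ARI-vs-silhouette scatter plots and a deterministic
`manifest.json` (config echo, library versions, per-stage counts, sha256 of
all structured outputs). Identical config + seed reproduce byte-identical
manifests.

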