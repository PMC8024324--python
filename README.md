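# visrsa

Representational-similarity analysis (RSA) of human visual-region response
geometries against model-layer geometries, implemented as a tested,
reusable pipeline:

- **geometry** — condition × unit response matrices → representational
  dissimilarity matrices (Euclidean distance of z-scored patterns, or
  correlation distance), their off-diagonal vectorization, and tie-aware
  Spearman / Pearson RDM comparison with Fisher z-transform.
- **voxels** — odd/even split-half reliability per voxel, top-*k* (default
  75) voxel selection, and category-selectivity flagging/exclusion via
  across-run one-tailed paired *t*-tests.
- **ceiling** — lower / upper group noise-ceiling bounds
  (leave-one-out vs. full group-mean RDM correlation).
- **inference** — the hierarchy-correspondence statistic (Spearman rho of
  region rank vs. best-layer index, Fisher-z, one-tailed group *t*),
  explainable-variance-captured proportions `(r / lower_ceiling)²` with the
  one-tailed vs-1 test, and Benjamini–Hochberg FDR control.
- **embedding** — classical (Torgerson) MDS to 2-D with Procrustes
  alignment (rotation/reflection only; distances preserved exactly).
- **simulate** — a synthetic-data generator planting a hierarchy of
  category geometries, a region→layer correspondence, subject variability,
  run noise, unreliable voxels, and category-selective voxels, so every
  stage is verifiable by parameter recovery.
- **pipeline / cli** — end-to-end orchestration from one JSON config with
  deterministic TSV/JSON report bundles, plus a method-variant concordance
  check.

## CLI

```sh
# generate a synthetic dataset (TSV beta series + layer matrices + manifest)
visrsa simulate --config examples/sim.json --seed 1 --out scratch/sim

# full analysis from one config document
visrsa run --config examples/analysis.json --out scratch/report

# agreement between euclidean_z/spearman and correlation/pearson variants
visrsa compare-variants --config examples/analysis.json --out scratch/agreement.tsv

# embed one RDM (square TSV) into 2-D
visrsa mds scratch/report/some_rdm.tsv --out scratch/coords.tsv
```

A minimal analysis config:

```json
{
  "simulation": {"n_subjects": 6, "n_regions": 6, "n_categories": 8,
                 "n_runs": 16, "n_voxels_per_region": 120,
                 "n_model_layers": 11, "seed": 1},
  "top_k": 75,
  "metric": "euclidean_z",
  "comparison": "spearman",
  "q": 0.05,
  "output_dir": "scratch/report"
}
```

The report bundle contains `ceilings.tsv`, `best_layers.tsv`,
`correspondence.tsv`, `capture_proportions.tsv`, `capture_tests.tsv`,
`correlations.tsv`, `mds_regions.tsv`, `mds_layers.tsv`,
`selection_log.tsv`, and a `manifest.json` with the verbatim config, seed,
and output hashes. Identical config + seed reproduce every table
byte-for-byte.

## Acceptance

Acceptance is property-based (oracle equivalence, planted-parameter
recovery, error-rate control) and lives in `tests/test_acceptance.py`.
The report script runs a small end-to-end pipeline as a liveness check and
writes the (empty) numeric-target report:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
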