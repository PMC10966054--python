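# statescape

Topological landscape analysis of multi-state brain-activity recordings.

The package turns per-subject labeled time × feature matrices (frames ×
voxel-surrogates, one state label per frame) into **Mapper shape graphs** and
compares their topology across groups and sessions:

- **`statescape.synthetic`** — a seeded cohort generator that emulates a
  6-state (RS/FA/OM × pre/post), two-group design with planted session and
  group effects, AR(1) temporally autocorrelated noise, and psychometric
  scores generated from the planted latents (ground truth retained for
  recovery tests). Also provides geometric toy clouds (noisy circles).
- **`statescape.mapper`** — Mapper construction: 2-D filter embedding
  (identity / linear projection / seeded UMAP-style manifold), overlapping
  rectangular cover (`b` divisions, overlap `p`), density-based clustering of
  each bin's preimage in the original feature space (global epsilon chosen so
  every point has ≥ k neighbors; noise points kept as singleton nodes), and
  cluster-overlap graph assembly.
- **`statescape.measures`** — label distributions over nodes, geodesic
  hop-count matrices, *exact* 1-Wasserstein optimal-transport distances
  (LP/min-cost-flow via HiGHS), label-weighted closeness/degree centrality,
  and label diameters.
- **`statescape.stats`** — mixed two-way ANOVA, Welch/paired t tests,
  Kendall/Pearson correlation matrices with an eigenvalue-based effective
  number of tests, Benjamini–Yekutieli FDR, random-intercept mixed linear
  models with marginal/conditional R², median-split tests, and the
  two-predictor insightfulness model.
- **`statescape.pipeline` / `statescape.cli`** — end-to-end orchestration
  with YAML configuration, per-run manifests, and full seed control.

## Test

```
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests for the package
invariants, and `tests/test_acceptance.py` with one test per acceptance
criterion (OT oracle equivalence against exhaustive enumeration, metric
axioms, statistical calibration, end-to-end parameter recovery on synthetic
cohorts, byte-level determinism).

## CLI

```
# generate a synthetic cohort as plain-text matrices + CSVs
statescape simulate --params params.yaml --out data/

# run the full pipeline (synthetic mode or from files)
statescape run --config config.yaml --out results/ --bins 30 --overlap 0.5

# descriptors of a single saved shape graph
statescape measure --graph results/graphs/sub-000.graphml
```

A minimal `config.yaml`:

```yaml
mode: synthetic
cohort:
  n_per_group: 18
  frames_per_state: 100
  seed: 1
bins: 30
overlap: 0.5
filter_method: linear
window: 100
out_dir: results/run1
```

Outputs per run: `measures.csv` (one row per subject, all topological
descriptors), `stats.csv` (the full test battery with raw and corrected
p-values), `correlations_r.csv` / `correlations_p.csv`, `manifest.json`
(config echo, per-subject graph summaries, exclusions), and per-subject
GraphML/JSON graphs.

## Notes

- The filter embedding is only a lens; clustering always happens in the
  original feature space with the Euclidean metric.
- Optimal transport is solved exactly (no entropic regularization).
  Distribution supports spanning several graph components raise an explicit
  error; the pipeline then restricts each subject's graph to its largest
  connected component and records the discarded frame fraction in the
  manifest.
- Determinism: identical configuration and seeds produce byte-identical
  `measures.csv` and `stats.csv`.
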