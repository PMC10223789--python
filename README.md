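# depnet

Network-biology-informed machine learning for predicting binary cancer
gene dependencies.

A gene dependency is a gene a cancer cell needs to keep growing: CRISPR
knockout screens (DepMap) quantify it with gene-effect scores scaled so
the median essential gene sits at −1 and the median nonessential gene at
0. `depnet` asks whether a gene's *position in a cancer type's gene
regulatory network* predicts whether that cancer depends on it — and
which network properties carry the signal.

## The pipeline

For each cancer lineage (cell lines grouped by CCLE cancer-type
annotation, lineages with < 3 lines excluded):

1. **Network inference** — a mutual-information (MI) network over the
   lineage's expression profiles, ARACNE-style: estimate MI for every
   gene pair, optionally prune each triangle's weakest edge via the data
   processing inequality (DPI), then drop edges with MI below a cutoff
   (default 1.5 on the study scale; the value is estimator-dependent and
   configurable). Estimators: equal-frequency binning with Miller–Madow
   correction, or a Gaussian-copula closed form
   MI = −½ ln(1 − ρ²) with ρ = 2 sin(π ρ_s/6).
2. **Feature engineering** — four classes per gene *g*:
   *traditional* (degree, average neighbor degree, Σ adjacent edge
   weights, betweenness, closeness), *hallmark* (|N(g) ∩ H_k| for each of
   the 10 cancer-hallmark gene sets), *shortest_path* (hop distance to
   each Cancer Gene Census gene), and *smallest_path* (minimum
   edge-weight-sum path to each CGC gene).
3. **Labeling** — per (gene, lineage): mean gene-effect score across the
   lineage's cell lines, binarized at −1 (mean ≤ −1 ⇒ dependent).
4. **Modeling** — ten scikit-learn classifiers at default
   hyperparameters, stratified 5-fold cross-validation, F1 of the
   dependent class (F1 = 2PR/(P+R)); feature-class ablations (4 single,
   6 pairwise), single-feature ablations, permutation importance, and
   sweeps over the dependency cutoff (−1.5 … 0.1) and the MI pruning
   cutoff.

A bundled synthetic-data generator produces a scale-free gene network,
expression with MI signal along true edges (linear-Gaussian structural
scheme), hub-biased CGC/hallmark-like gene sets, and dependency scores
planted as a noisy decreasing function of chosen network features — so
every stage can be tested against known ground truth at desk scale.

## Worked example

```python
from depnet import (SyntheticConfig, generate_dataset, ModelSpec,
                    crossval_f1, ablate_classes, permutation_importance)

cfg = SyntheticConfig(noise_sd=0.25, seed=1)   # 500 genes, 3 lineages
ds = generate_dataset(cfg)                     # planted: degree + one hallmark count
y = ds.truth_labels.for_lineage("lineage_01")

res = crossval_f1(ds.features, y, ModelSpec("logistic_regression", seed=1), seed=1)
print(f"cross-validated F1: {res.f1_mean:.3f} +/- {res.f1_sd:.3f}")
for r in ablate_classes(ds.features, y, ModelSpec(seed=1), arity=1, seed=1):
    print(f"ablate {r.removed[0]:>13}: F1 {r.f1_mean:.3f} (delta {r.delta_vs_full:+.3f})")
```

prints

```
cross-validated F1: 0.935 +/- 0.033
ablate   traditional: F1 0.884 (delta -0.051)
ablate      hallmark: F1 0.641 (delta -0.294)
ablate shortest_path: F1 0.921 (delta -0.014)
ablate smallest_path: F1 0.943 (delta +0.008)
```

The planted signal (an effect on node degree and on the count of
resisting-cell-death hallmark neighbors) is recovered: the model predicts
the 74/500 dependent genes at F1 0.935, and ablating the hallmark class —
which holds the strongest planted driver — costs by far the most F1.
Permutation importance ranks that driver first:

```
feature_class              feature  importance_mean
     hallmark resisting_cell_death            0.439
  traditional sum_adjacent_weights            0.092
  traditional               degree            0.054
```

The same analyses are available from the shell via the `depnet` command
(`simulate`, `infer-network`, `features`, `label`, `train`, `ablate`,
`importance`, `sweep`, `run`); `depnet --help` lists them.
`scripts/run_depmap_pipeline.py` documents how to run the full pipeline
on locally downloaded DepMap/CCLE inputs (not bundled; license-gated).

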