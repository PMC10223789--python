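#!/usr/bin/env python
"""Optional end-to-end driver for the real DepMap/CCLE corpus.

This script is NOT part of the test suite: it requires locally downloaded
inputs that are license-gated and several gigabytes in size:

* CCLE log2(TPM+1) expression, genes x cell lines (TSV/CSV);
* DepMap 21Q3 CRISPR gene-effect scores, genes x cell lines, on the scale
  where the median essential gene is -1 and the median nonessential 0;
* a cell-line annotation table mapping cell line -> lineage;
* the 10 COSMIC CGC hallmark gene sets (GMT) and the CGC gene list;
* optionally a cohort index restricting cell lines (one id per line).

It applies the study settings: lineages with fewer than 3 cell lines are
excluded, networks are pruned at MI >= 1.5 (2.0 for oesophagus, whose
dense network is otherwise impractical), labels binarized at -1, and the
full model zoo evaluated per lineage with 5-fold cross-validated F1.

Example:
    python scripts/run_depmap_pipeline.py \
        --expression CCLE_expression.tsv --scores CRISPR_gene_effect.tsv \
        --annotations sample_info.tsv --hallmarks cgc_hallmarks.gmt \
        --cgc cgc_genes.txt --outdir runs/depmap21q3 --seed 0
"""

import argparse

from depnet.network import InferenceConfig
from depnet.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--expression", required=True)
    parser.add_argument("--scores", required=True)
    parser.add_argument("--annotations", required=True)
    parser.add_argument("--hallmarks", required=True)
    parser.add_argument("--cgc", required=True)
    parser.add_argument("--cohort-index", default=None)
    parser.add_argument("--outdir", required=True)
    parser.add_argument("--mi-cutoff", type=float, default=1.5)
    parser.add_argument("--oesophagus-cutoff", type=float, default=2.0)
    parser.add_argument("--oesophagus-lineage", default="oesophagus",
                        help="Lineage name carrying the raised cutoff.")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    config = PipelineConfig(
        expression_path=args.expression,
        scores_path=args.scores,
        annotations_path=args.annotations,
        hallmark_gmt=args.hallmarks,
        cgc_path=args.cgc,
        cohort_index_path=args.cohort_index,
        outdir=args.outdir,
        inference=InferenceConfig(
            mi_cutoff=args.mi_cutoff,
            per_lineage_cutoff_override={args.oesophagus_lineage: args.oesophagus_cutoff},
        ),
        label_cutoff=-1.0,
        models=tuple(
            sorted(
                (
                    "adaboost", "decision_tree", "gaussian_process", "knn",
                    "linear_svc", "logistic_regression", "random_forest",
                    "ridge", "sgd_linear_svc", "rbf_svc",
                )
            )
        ),
        seed=args.seed,
    )
    manifest = run_pipeline(config)
    print(f"pipeline finished; manifest at {args.outdir}/manifest.json")
    for stage, status in manifest["stages"].items():
        print(f"  {stage}: {status}")


if __name__ == "__main__":
    main()
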