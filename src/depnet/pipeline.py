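"""End-to-end driver: files in, per-lineage artifacts and reports out.

Stages: cohort filtering -> per-lineage MI network inference (DPI + MI
cutoff) -> four-class feature computation -> dependency labeling ->
cross-validated model evaluation.  Every run writes a manifest recording
the package version, seed, configuration hash, and per-stage status;
stage failures are recorded and later stages for that lineage skipped,
but other lineages continue.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .datatypes import ExpressionMatrix, DependencyScores, GeneSetCollection
from .features import compute_network_features, expression_summary_features, assemble_features
from .io import (
    apply_cohort_filters,
    read_expression,
    read_gene_sets,
    read_lineage_annotations,
    read_scores,
    write_feature_table,
    write_labels,
    write_network,
)
from .labeling import aggregate_scores, binarize
from .modeling import MODEL_ZOO, run_model_zoo
from .network import InferenceConfig, infer_pruned_network

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and settings for a full run; see the CLI for file formats."""

    expression_path: str
    scores_path: str
    annotations_path: str
    hallmark_gmt: str
    cgc_path: str
    outdir: str
    cohort_index_path: str | None = None
    min_lines: int = 3
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    label_cutoff: float = -1.0
    path_mode: str = "raw"
    models: tuple[str, ...] = ("logistic_regression",)
    feature_sets: tuple[str, ...] = ("network", "expression", "combined")
    cv_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        for attr in ("expression_path", "scores_path", "annotations_path",
                     "hallmark_gmt", "cgc_path"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        unknown = set(self.models) - set(MODEL_ZOO)
        if unknown:
            raise ValueError(f"unknown model name(s): {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["inference"] = asdict(self.inference)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "label_cutoff": config.label_cutoff,
        "stages": {},
        "lineages": {},
    }

    def record(stage: str, status: str) -> None:
        manifest["stages"][stage] = status
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        lineage_of = read_lineage_annotations(config.annotations_path)
        expr = read_expression(config.expression_path, lineage_of)
        scores = read_scores(config.scores_path, lineage_of)
        gene_sets = read_gene_sets(config.hallmark_gmt, config.cgc_path)
        cohort = None
        if config.cohort_index_path:
            cohort = [
                line.strip()
                for line in Path(config.cohort_index_path).read_text().splitlines()
                if line.strip()
            ]
        expr, scores = apply_cohort_filters(expr, scores, cohort, config.min_lines)
        record("load_and_filter", "ok")
    except Exception as exc:
        record("load_and_filter", f"error: {exc}")
        raise

    for lineage in expr.lineages():
        status = _run_lineage(config, expr, scores, gene_sets, lineage, outdir)
        manifest["lineages"][lineage] = status
        record(f"lineage:{lineage}", status.get("overall", "error"))
    record("pipeline", "ok")
    return manifest


def _run_lineage(
    config: PipelineConfig,
    expr: ExpressionMatrix,
    scores: DependencyScores,
    gene_sets: GeneSetCollection,
    lineage: str,
    outdir: Path,
) -> dict:
    status: dict = {}
    try:
        net = infer_pruned_network(expr, lineage, config.inference)
        write_network(net, outdir / f"network_{lineage}.tsv")
        status["network"] = f"ok ({net.number_of_nodes()} nodes, {net.number_of_edges()} edges)"
    except Exception as exc:
        logger.exception("network inference failed for %s", lineage)
        status.update(network=f"error: {exc}", overall="error")
        return status

    try:
        expr_summary = expression_summary_features(expr, lineage)
        feats = compute_network_features(net, gene_sets, path_mode=config.path_mode)
        feats = assemble_features([feats], expr_summary)
        write_feature_table(feats, outdir / f"features_{lineage}.csv")
        status["features"] = f"ok ({feats.data.shape[1]} columns)"
    except Exception as exc:
        logger.exception("feature computation failed for %s", lineage)
        status.update(features=f"error: {exc}", overall="error")
        return status

    try:
        means = aggregate_scores(scores, lineage, config.min_lines)
        labels = binarize(means, cutoff=config.label_cutoff, lineage=lineage)
        write_labels(labels, outdir / f"labels_{lineage}.csv")
        status["labels"] = f"ok ({int(labels.table['label'].sum())} dependent)"
    except Exception as exc:
        logger.exception("labeling failed for %s", lineage)
        status.update(labels=f"error: {exc}", overall="error")
        return status

    try:
        report = run_model_zoo(
            feats,
            labels.for_lineage(lineage),
            feature_sets=tuple(config.feature_sets),
            models=tuple(config.models),
            k=config.cv_folds,
            seed=config.seed,
        )
        report.insert(0, "lineage", lineage)
        out = report.drop(columns=["fold_scores"]).assign(
            fold_scores=[json.dumps(f) for f in report["fold_scores"]]
        )
        out.to_csv(outdir / f"evaluation_{lineage}.csv", index=False)
        status["evaluation"] = "ok"
        status["overall"] = "ok"
    except Exception as exc:
        logger.exception("evaluation failed for %s", lineage)
        status.update(evaluation=f"error: {exc}", overall="error")
    return status
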