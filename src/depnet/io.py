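"""File readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV/CSV (genes as rows, header row of sample ids),
gene sets as GMT, networks as 3-column edge lists or GraphML, feature
tables as CSV with a two-row header carrying the class tag and the
feature name, and labels/reports as tidy CSV.  Readers validate rather
than silently coerce: malformed numeric fields and structural problems
raise; rows with missing values are dropped with a logged count
(expression completeness filter).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    DependencyLabels,
    DependencyScores,
    ExpressionMatrix,
    FeatureTable,
    GeneSetCollection,
    ValidationError,
)

logger = logging.getLogger(__name__)


def _sniff_delimiter(path: Path, override: str | None = None) -> str:
    if override is not None:
        if override not in ("\t", ","):
            raise ValueError("delimiter must be tab or comma")
        return override
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_matrix(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValidationError(f"missing or empty file: {path}")
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValidationError(f"no data rows in {path}")
    if df.index.has_duplicates:
        raise ValidationError(f"duplicate gene ids in {path}")
    if df.columns.has_duplicates:
        raise ValidationError(f"duplicate sample ids in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"malformed numeric field in {path}: {exc}") from None
    df.index.name = None  # in-memory matrices keep an unnamed gene index
    return df


def read_lineage_annotations(path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    """Two-column (sample, lineage) table -> mapping."""
    path = Path(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"annotation file {path} needs (sample, lineage) columns")
    sample_col, lineage_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        raise ValidationError(f"duplicate sample ids in {path}")
    return dict(zip(df[sample_col], df[lineage_col]))


def read_expression(
    path: str | Path,
    lineage_of: Mapping[str, str],
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Load a genes x samples expression matrix.

    Genes with any missing value are dropped with a logged count,
    mirroring the completeness filter applied to the real corpus.
    """
    df = _read_matrix(path, delimiter)
    incomplete = df.isna().any(axis=1)
    if incomplete.any():
        logger.info(
            "read_expression: dropped %d genes with missing values", int(incomplete.sum())
        )
        df = df[~incomplete]
    if df.empty:
        raise ValidationError(f"all genes in {path} had missing values")
    return ExpressionMatrix(values=df, lineage_of=dict(lineage_of))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_scores(
    path: str | Path,
    lineage_of: Mapping[str, str],
    delimiter: str | None = None,
) -> DependencyScores:
    df = _read_matrix(path, delimiter)
    incomplete = df.isna().any(axis=1)
    if incomplete.any():
        logger.info("read_scores: dropped %d genes with missing values", int(incomplete.sum()))
        df = df[~incomplete]
    return DependencyScores(values=df, lineage_of=dict(lineage_of))


def write_scores(scores: DependencyScores, path: str | Path) -> None:
    scores.values.to_csv(path, sep="\t", index_label="gene")


def write_lineage_annotations(lineage_of: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(lineage_of), "lineage": list(lineage_of.values())}
    ).to_csv(path, sep="\t", index=False)


def _parse_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT line {lineno} needs name, description, and >=1 member"
                )
            name, members = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValidationError(f"duplicate gene set {name!r} in GMT")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.info(
                    "gene set %s: removed %d duplicate members",
                    name,
                    len(members) - len(deduped),
                )
            sets[name] = deduped
    if not sets:
        raise ValidationError(f"empty GMT file: {path}")
    return sets


def read_gene_sets(
    hallmark_gmt: str | Path, cgc_path: str | Path
) -> GeneSetCollection:
    """Hallmark sets from GMT (must contain exactly 10) plus the CGC list.

    The CGC file may be a one-column text list (optionally a second
    tab-separated tier column) or a GMT whose sets are unioned.
    """
    hallmark_raw = _parse_gmt(hallmark_gmt)
    if len(hallmark_raw) != 10:
        raise ValidationError(
            f"hallmark GMT must contain exactly 10 sets, found {len(hallmark_raw)}"
        )
    hallmarks = {name: frozenset(members) for name, members in hallmark_raw.items()}

    cgc_path = Path(cgc_path)
    with open(cgc_path) as fh:
        first = fh.readline()
    if first.count("\t") >= 2:  # GMT-shaped
        cgc_sets = _parse_gmt(cgc_path)
        cgc = list(dict.fromkeys(g for members in cgc_sets.values() for g in members))
        tiers = None
    else:
        cgc, tiers = [], {}
        with open(cgc_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                gene = fields[0]
                if gene in tiers:
                    logger.info("duplicate CGC gene %s ignored", gene)
                    continue
                cgc.append(gene)
                tiers[gene] = int(fields[1]) if len(fields) > 1 else 1
        if not tiers:
            tiers = None
    return GeneSetCollection(hallmark_sets=hallmarks, cgc_genes=cgc, cgc_tiers=tiers)


def write_gene_sets(sets: GeneSetCollection, hallmark_gmt: str | Path, cgc_path: str | Path) -> None:
    with open(hallmark_gmt, "w") as fh:
        for name, members in sets.hallmark_sets.items():
            fh.write("\t".join([name, "hallmark", *sorted(members)]) + "\n")
    with open(cgc_path, "w") as fh:
        for g in sets.cgc_genes:
            tier = (sets.cgc_tiers or {}).get(g, 1)
            fh.write(f"{g}\t{tier}\n")


def read_network(path: str | Path) -> nx.Graph:
    """3-column (gene_a, gene_b, mi) edge-list TSV, or GraphML by suffix."""
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(path)
        return nx.relabel_nodes(g, str)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValidationError(f"edge list {path} needs (gene_a, gene_b, mi) columns")
    g = nx.Graph()
    for a, b, w in df.itertuples(index=False):
        w = float(w)
        if w < 0:
            raise ValidationError(f"negative edge weight {w} in {path}")
        g.add_edge(str(a), str(b), weight=w)
    return g


def write_network(net: nx.Graph, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(net, path)
        return
    rows = [(u, v, w) for u, v, w in net.edges(data="weight")]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi"]).to_csv(
        path, sep="\t", index=False
    )


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, header=[0, 1], index_col=0)
    df.index.name = None
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.data.to_csv(path, index_label="gene")


def read_labels(path: str | Path) -> DependencyLabels:
    df = pd.read_csv(path)
    cutoffs = df["cutoff_used"].unique() if "cutoff_used" in df else [-1.0]
    if len(cutoffs) != 1:
        raise ValidationError("labels file mixes cutoffs")
    df = df[["gene", "lineage", "mean_score", "label"]]
    return DependencyLabels(df, cutoff_used=float(cutoffs[0]))


def write_labels(labels: DependencyLabels, path: str | Path) -> None:
    out = labels.table.copy()
    out["cutoff_used"] = labels.cutoff_used
    out.to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg


def apply_cohort_filters(
    expr: ExpressionMatrix,
    scores: DependencyScores,
    cohort_index: Iterable[str] | None = None,
    min_lines: int = 3,
) -> tuple[ExpressionMatrix, DependencyScores]:
    """Restrict to the shared cohort and drop under-populated lineages.

    Samples must appear in both matrices (and in ``cohort_index`` when
    given); lineages retaining fewer than ``min_lines`` samples are
    removed.  Gene universes are intersected.  Every filter logs its
    count; an empty intersection is an error.
    """
    samples = [s for s in expr.sample_ids if s in set(scores.values.columns)]
    if cohort_index is not None:
        allowed = set(cohort_index)
        samples = [s for s in samples if s in allowed]
    if not samples:
        raise ValidationError("no samples shared between expression, scores, and cohort")
    logger.info(
        "cohort filter: %d of %d expression samples retained", len(samples), len(expr.sample_ids)
    )

    counts: dict[str, int] = {}
    for s in samples:
        counts[expr.lineage_of[s]] = counts.get(expr.lineage_of[s], 0) + 1
    kept_lineages = {l for l, c in counts.items() if c >= min_lines}
    dropped = sorted(set(counts) - kept_lineages)
    if dropped:
        logger.info("excluding %d lineages with < %d lines: %s", len(dropped), min_lines, dropped)
    samples = [s for s in samples if expr.lineage_of[s] in kept_lineages]
    if not samples:
        raise ValidationError(f"no lineage retains >= {min_lines} samples")

    genes = [g for g in expr.gene_ids if g in set(scores.values.index)]
    if not genes:
        raise ValidationError("no genes shared between expression and scores")
    logger.info("gene intersection: %d of %d expression genes retained", len(genes), len(expr.gene_ids))

    lineage_of = {s: expr.lineage_of[s] for s in samples}
    return (
        ExpressionMatrix(values=expr.values.loc[genes, samples], lineage_of=lineage_of),
        DependencyScores(values=scores.values.loc[genes, samples], lineage_of=lineage_of),
    )
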