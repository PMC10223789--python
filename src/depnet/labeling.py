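"""Lineage-level aggregation and binarization of CRISPR dependency scores.

A gene's label within a cancer type is derived from the arithmetic mean of
its gene-effect scores across that type's cell lines: means at or below
the cutoff (default -1, the median score of ubiquitously essential genes
on the DepMap scale) are called dependent, everything above non-dependent.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .datatypes import DependencyLabels, DependencyScores

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = -1.0
MIN_LINES_PER_LINEAGE = 3


def aggregate_scores(
    scores: DependencyScores, lineage: str, min_lines: int = MIN_LINES_PER_LINEAGE
) -> pd.Series:
    """Mean gene-effect score per gene over one lineage's cell lines.

    Lineages with fewer than ``min_lines`` cell lines are rejected,
    mirroring the cohort exclusion applied upstream.
    """
    samples = scores.samples_in(lineage)
    if len(samples) < min_lines:
        raise ValueError(
            f"lineage {lineage!r} has {len(samples)} cell lines; need >= {min_lines}"
        )
    return scores.values[samples].mean(axis=1)


def binarize(means: Mapping[str, float] | pd.Series, cutoff: float = DEFAULT_CUTOFF,
             lineage: str = "all") -> DependencyLabels:
    """Binary dependent / non-dependent call from lineage-mean scores.

    A mean exactly at the cutoff is labeled dependent (scores below or
    equal to the cutoff count as dependent).
    """
    means = pd.Series(means, dtype=float)
    table = pd.DataFrame(
        {
            "gene": means.index,
            "lineage": lineage,
            "mean_score": means.to_numpy(),
            "label": (means.to_numpy() <= cutoff).astype(int),
        }
    )
    return DependencyLabels(table, cutoff_used=cutoff)


def label_all_lineages(
    scores: DependencyScores,
    cutoff: float = DEFAULT_CUTOFF,
    min_lines: int = MIN_LINES_PER_LINEAGE,
) -> DependencyLabels:
    """Aggregate and binarize every lineage with enough cell lines."""
    frames = []
    for lineage in scores.lineages():
        n = len(scores.samples_in(lineage))
        if n < min_lines:
            logger.info("skipping lineage %s with %d < %d lines", lineage, n, min_lines)
            continue
        means = aggregate_scores(scores, lineage, min_lines)
        frames.append(binarize(means, cutoff, lineage).table)
    if not frames:
        raise ValueError("no lineage satisfies the minimum cell-line count")
    return DependencyLabels(pd.concat(frames, ignore_index=True), cutoff_used=cutoff)
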