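"""Core data containers shared across the pipeline.

The pipeline moves four kinds of data between stages: a log-scale
expression matrix with lineage (cancer-type) annotations, an undirected
mutual-information gene network, a per-gene feature table partitioned into
tagged feature classes, and CRISPR dependency scores with their binarized
per-lineage labels.  Matrices are held as pandas DataFrames (genes as rows,
samples as columns); networks are ``networkx.Graph`` objects with a
``weight`` attribute on every edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: The four engineered network-feature classes, plus the optional
#: expression summary class appended by :func:`depnet.features.assemble_features`.
NETWORK_FEATURE_CLASSES = ("traditional", "hallmark", "shortest_path", "smallest_path")
ALL_FEATURE_CLASSES = NETWORK_FEATURE_CLASSES + ("expression",)


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples continuous (log-scale) expression with lineage labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.  No
        missing values are allowed; rows containing any are rejected at
        construction (readers drop them with a logged count before
        constructing this object).
    lineage_of
        Mapping from sample id to lineage name.  Every sample column must
        be annotated.
    """

    values: pd.DataFrame
    lineage_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in expression matrix")
        missing = [s for s in self.values.columns if s not in self.lineage_of]
        if missing:
            raise ValidationError(
                f"{len(missing)} samples lack a lineage annotation "
                f"(first: {missing[0]!r})"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def lineages(self) -> list[str]:
        """Lineage names present, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.lineage_of[s], None)
        return list(seen)

    def samples_in(self, lineage: str) -> list[str]:
        out = [s for s in self.values.columns if self.lineage_of[s] == lineage]
        if not out:
            raise KeyError(f"unknown lineage {lineage!r}")
        return out

    def subset(self, lineage: str) -> pd.DataFrame:
        """Genes x samples sub-matrix for one lineage."""
        return self.values[self.samples_in(lineage)]


@dataclass
class DependencyScores:
    """CRISPR gene-effect scores, genes x cell lines.

    Scores follow the DepMap convention: scaled so the median essential
    gene sits at -1 and the median nonessential gene at 0; more negative
    means stronger dependency.
    """

    values: pd.DataFrame
    lineage_of: Mapping[str, str]

    def __post_init__(self) -> None:
        import numpy as np

        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("dependency scores contain non-finite values")
        missing = [s for s in self.values.columns if s not in self.lineage_of]
        if missing:
            raise ValidationError(
                f"{len(missing)} score samples lack a lineage annotation"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def lineages(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.lineage_of[s], None)
        return list(seen)

    def samples_in(self, lineage: str) -> list[str]:
        out = [s for s in self.values.columns if self.lineage_of[s] == lineage]
        if not out:
            raise KeyError(f"unknown lineage {lineage!r}")
        return out


@dataclass
class GeneSetCollection:
    """Hallmark gene sets plus the cancer-census gene list.

    ``hallmark_sets`` maps each of the 10 cancer hallmark categories to its
    member genes; ``cgc_genes`` is the ordered Cancer Gene Census list,
    optionally annotated with evidence tiers.
    """

    hallmark_sets: dict[str, frozenset[str]]
    cgc_genes: list[str]
    cgc_tiers: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.hallmark_sets) != 10:
            raise ValidationError(
                f"expected exactly 10 hallmark sets, got {len(self.hallmark_sets)}"
            )
        if not self.cgc_genes:
            raise ValidationError("cancer-census gene list is empty")
        if len(set(self.cgc_genes)) != len(self.cgc_genes):
            raise ValidationError("duplicate genes in cancer-census list")

    def cgc_subset(self, max_tier: int | None) -> list[str]:
        """CGC genes at or below an evidence tier (all genes if no filter)."""
        if max_tier is None or self.cgc_tiers is None:
            return list(self.cgc_genes)
        return [g for g in self.cgc_genes if self.cgc_tiers.get(g, 1) <= max_tier]


@dataclass
class FeatureTable:
    """Per-gene feature matrix with class-tagged columns.

    ``data`` uses a two-level column MultiIndex ``(feature_class,
    feature_name)`` so that whole classes can be selected or ablated by
    tag.  ``sentinel_policy`` records how unreachable path distances were
    encoded, keyed by feature class.
    """

    data: pd.DataFrame
    sentinel_policy: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex) or self.data.columns.nlevels != 2:
            raise ValidationError("feature columns must be a (class, name) MultiIndex")
        if self.data.isna().any().any():
            raise ValidationError("feature table contains missing values")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate feature columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.data.columns.get_level_values(0):
            seen.setdefault(c, None)
        return list(seen)

    def select_classes(self, classes: Iterable[str]) -> "FeatureTable":
        classes = list(classes)
        unknown = set(classes) - set(self.classes)
        if unknown:
            raise KeyError(f"unknown feature class(es): {sorted(unknown)}")
        cols = [c for c in self.data.columns if c[0] in classes]
        return FeatureTable(self.data[cols], dict(self.sentinel_policy))

    def drop_classes(self, classes: Iterable[str]) -> "FeatureTable":
        classes = list(classes)
        unknown = set(classes) - set(self.classes)
        if unknown:
            raise KeyError(f"unknown feature class(es): {sorted(unknown)}")
        cols = [c for c in self.data.columns if c[0] not in classes]
        return FeatureTable(self.data[cols], dict(self.sentinel_policy))

    def drop_feature(self, name: str) -> "FeatureTable":
        cols = [c for c in self.data.columns if c[1] != name]
        if len(cols) == len(self.data.columns):
            raise KeyError(f"unknown feature {name!r}")
        return FeatureTable(self.data[cols], dict(self.sentinel_policy))

    def align_to(self, genes: Iterable[str]) -> "FeatureTable":
        """Restrict rows to ``genes`` (order preserved); missing genes error."""
        genes = list(genes)
        missing = set(genes) - set(self.data.index)
        if missing:
            raise KeyError(f"{len(missing)} genes absent from feature table")
        return FeatureTable(self.data.loc[genes], dict(self.sentinel_policy))


@dataclass
class DependencyLabels:
    """Binarized per-(gene, lineage) dependency calls.

    ``table`` has columns ``gene``, ``lineage``, ``mean_score``, ``label``
    where ``label`` is 1 for dependent and 0 for non-dependent.  A gene is
    dependent exactly when its lineage-mean score is less than or equal to
    ``cutoff_used``.
    """

    table: pd.DataFrame
    cutoff_used: float

    def __post_init__(self) -> None:
        required = {"gene", "lineage", "mean_score", "label"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"labels table must have columns {sorted(required)}")
        expected = (self.table["mean_score"] <= self.cutoff_used).astype(int)
        if not (self.table["label"].astype(int) == expected).all():
            raise ValidationError("labels inconsistent with mean_score and cutoff")

    def for_lineage(self, lineage: str) -> pd.Series:
        """Binary label Series indexed by gene for one lineage."""
        sub = self.table[self.table["lineage"] == lineage]
        if sub.empty:
            raise KeyError(f"unknown lineage {lineage!r}")
        return sub.set_index("gene")["label"].astype(int)

    def means_for_lineage(self, lineage: str) -> pd.Series:
        sub = self.table[self.table["lineage"] == lineage]
        if sub.empty:
            raise KeyError(f"unknown lineage {lineage!r}")
        return sub.set_index("gene")["mean_score"].astype(float)


def new_gene_network(nodes: Iterable[str] = ()) -> nx.Graph:
    """Fresh undirected gene network; edges carry a ``weight`` attribute."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    return g


def validate_gene_network(net: nx.Graph) -> nx.Graph:
    """Check the gene-network contract: undirected, no self-loops, weights >= 0."""
    if net.is_directed():
        raise ValidationError("gene network must be undirected")
    if any(u == v for u, v in net.edges):
        raise ValidationError("gene network contains self-loops")
    for u, v, d in net.edges(data=True):
        w = d.get("weight")
        if w is None or w < 0:
            raise ValidationError(f"edge ({u!r}, {v!r}) has invalid weight {w!r}")
    return net
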