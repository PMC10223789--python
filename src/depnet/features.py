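"""Engineered network features for every gene in a pruned lineage network.

Four feature classes are computed per gene:

1. ``traditional`` — five classical topology measures: degree, average
   first-neighbor degree, sum of adjacent edge weights, betweenness
   centrality, and closeness centrality.
2. ``hallmark`` — the number of first-degree neighbors belonging to each
   of the 10 cancer hallmark gene sets.
3. ``shortest_path`` — minimum hop count to each cancer-census (CGC) gene.
4. ``smallest_path`` — minimum-cost path to each CGC gene where the cost of
   a path is the sum of its edge weights (``raw`` mode) or of their
   reciprocals (``inverse`` mode, the "strong edge = short distance"
   convention).

Unreachable path distances receive finite sentinels so downstream models
stay trainable: the node count for hop features and (total edge weight + 1)
for weight features — both strictly larger than any achievable value.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, FeatureTable, GeneSetCollection

logger = logging.getLogger(__name__)

TRADITIONAL_FEATURES = (
    "degree",
    "avg_neighbor_degree",
    "sum_adjacent_weights",
    "betweenness",
    "closeness",
)

PATH_MODES = ("raw", "inverse")


def traditional_features(net: nx.Graph) -> FeatureTable:
    """The five classical topology measures, one row per gene.

    Betweenness and closeness are computed unweighted in their normalized
    forms (closeness with per-component normalization, the networkx
    Wasserman-Faust-free default restricted to reachable nodes).  Isolated
    nodes get zeros throughout.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    nodes = list(net.nodes)
    degree = dict(net.degree())
    avg_nbr = nx.average_neighbor_degree(net)
    weighted_degree = dict(net.degree(weight="weight"))
    betweenness = nx.betweenness_centrality(net, normalized=True)
    closeness = nx.closeness_centrality(net)
    data = pd.DataFrame(
        {
            ("traditional", "degree"): [float(degree[g]) for g in nodes],
            ("traditional", "avg_neighbor_degree"): [
                float(avg_nbr[g]) if degree[g] > 0 else 0.0 for g in nodes
            ],
            ("traditional", "sum_adjacent_weights"): [
                float(weighted_degree[g]) for g in nodes
            ],
            ("traditional", "betweenness"): [float(betweenness[g]) for g in nodes],
            ("traditional", "closeness"): [float(closeness[g]) for g in nodes],
        },
        index=nodes,
    )
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    return FeatureTable(data)


def hallmark_neighbor_counts(net: nx.Graph, sets: GeneSetCollection) -> FeatureTable:
    """Count of first-degree neighbors in each of the 10 hallmark sets.

    A gene's own membership is not counted; each count is bounded by the
    gene's degree.
    """
    nodes = list(net.nodes)
    columns = {}
    for name, members in sets.hallmark_sets.items():
        columns[("hallmark", name)] = [
            float(sum(1 for nbr in net[g] if nbr in members)) for g in nodes
        ]
    data = pd.DataFrame(columns, index=nodes)
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    return FeatureTable(data)


def _path_table(
    net: nx.Graph,
    cgc: Sequence[str],
    feature_class: str,
    lengths_from: dict[str, dict[str, float]],
    sentinel: float,
) -> FeatureTable:
    nodes = list(net.nodes)
    columns = {}
    for target in cgc:
        dists = lengths_from.get(target, {})
        columns[(feature_class, f"{feature_class}_to_{target}")] = [
            float(dists.get(g, sentinel)) for g in nodes
        ]
    data = pd.DataFrame(columns, index=nodes)
    data.columns = pd.MultiIndex.from_tuples(columns.keys())
    return FeatureTable(data, sentinel_policy={feature_class: sentinel})


def shortest_path_features(
    net: nx.Graph, sets: GeneSetCollection, max_tier: int | None = None
) -> FeatureTable:
    """Minimum hop count from every gene to every CGC gene.

    Distance to self is 0.  CGC genes absent from the network, and genes
    unreachable from a CGC gene, get the sentinel ``|nodes|``.
    """
    cgc = sets.cgc_subset(max_tier)
    sentinel = float(net.number_of_nodes())
    lengths = {
        t: dict(nx.single_source_shortest_path_length(net, t))
        for t in cgc
        if t in net
    }
    return _path_table(net, cgc, "shortest_path", lengths, sentinel)


def smallest_weight_path_features(
    net: nx.Graph,
    sets: GeneSetCollection,
    mode: str = "raw",
    max_tier: int | None = None,
) -> FeatureTable:
    """Minimum-cost path from every gene to every CGC gene.

    ``mode='raw'`` minimizes the sum of MI edge weights along the path
    (the literal smallest-weight path); ``mode='inverse'`` uses 1/weight
    as the edge cost so that strong interactions read as short distances.
    All edge weights must be positive.  Unreachable pairs get the sentinel
    (sum of all edge costs) + 1.
    """
    if mode not in PATH_MODES:
        raise ValueError(f"mode must be one of {PATH_MODES}, got {mode!r}")
    costs = []
    for u, v, w in net.edges(data="weight"):
        if w is None or w <= 0:
            raise ValueError(f"edge ({u!r}, {v!r}) has nonpositive weight {w!r}")
        costs.append(w if mode == "raw" else 1.0 / w)
    work = net.copy()
    for (u, v), c in zip(net.edges, costs):
        work[u][v]["cost"] = c
    sentinel = float(sum(costs)) + 1.0
    cgc = sets.cgc_subset(max_tier)
    lengths = {
        t: nx.single_source_dijkstra_path_length(work, t, weight="cost")
        for t in cgc
        if t in work
    }
    return _path_table(net, cgc, "smallest_path", lengths, sentinel)


def expression_summary_features(
    expr: ExpressionMatrix, lineage: str
) -> FeatureTable:
    """Per-gene mean and standard deviation of expression within a lineage.

    This is the compact per-gene encoding used for the "expression"
    feature set when instances are genes rather than samples.
    """
    sub = expr.subset(lineage)
    data = pd.DataFrame(
        {
            ("expression", "expr_mean"): sub.mean(axis=1),
            ("expression", "expr_sd"): sub.std(axis=1, ddof=1),
        }
    )
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    return FeatureTable(data)


def assemble_features(
    parts: Sequence[FeatureTable],
    expression_summary: FeatureTable | None = None,
) -> FeatureTable:
    """Column-concatenate feature tables over a common gene universe.

    All parts must cover the same genes after alignment to the first
    part's index; genes missing from any part are dropped with a logged
    count.  Duplicate column names are an error.
    """
    parts = list(parts)
    if expression_summary is not None:
        parts.append(expression_summary)
    if not parts:
        raise ValueError("no feature tables to assemble")
    common = parts[0].data.index
    for p in parts[1:]:
        common = common.intersection(p.data.index)
    dropped = len(parts[0].data.index) - len(common)
    if dropped:
        logger.info("assemble_features: dropped %d genes absent from some part", dropped)
    ordered = [g for g in parts[0].data.index if g in set(common)]
    data = pd.concat([p.data.loc[ordered] for p in parts], axis=1)
    if data.columns.has_duplicates:
        dupes = data.columns[data.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature columns: {dupes[:5]}")
    policy: dict[str, float] = {}
    for p in parts:
        policy.update(p.sentinel_policy)
    return FeatureTable(data, policy)


def compute_network_features(
    net: nx.Graph,
    sets: GeneSetCollection,
    path_mode: str = "raw",
    max_tier: int | None = None,
    expression_summary: FeatureTable | None = None,
) -> FeatureTable:
    """All four network feature classes (plus optional expression summary)."""
    parts = [
        traditional_features(net),
        hallmark_neighbor_counts(net, sets),
        shortest_path_features(net, sets, max_tier),
        smallest_weight_path_features(net, sets, path_mode, max_tier),
    ]
    return assemble_features(parts, expression_summary)
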