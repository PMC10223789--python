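"""Synthetic data with the statistical structure the pipeline assumes.

The generator plants a known signal and hands every pipeline stage an
input it can be tested against:

* a scale-free gene network (preferential attachment) with MI-like edge
  weights — the ground-truth interaction structure;
* an expression matrix sampled from a linear-Gaussian structural scheme
  over a random acyclic orientation of that network, so genes joined by a
  true edge are statistically dependent and MI-based inference can
  recover the edge;
* cancer-census-like ("CGC") and 10 hallmark-like gene sets, sampled
  disjointly and (by default) biased toward hubs, since cancer genes tend
  to sit in well-connected network positions;
* continuous dependency scores built as a noisy monotone function of a
  chosen set of network features, with the offset calibrated so a target
  fraction of genes falls at or below the dependency cutoff of -1.

All draws are deterministic functions of ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    DependencyLabels,
    DependencyScores,
    ExpressionMatrix,
    FeatureTable,
    GeneSetCollection,
)
from .features import compute_network_features
from .labeling import DEFAULT_CUTOFF

logger = logging.getLogger(__name__)

#: Default hallmark category names (COSMIC CGC hallmark vocabulary).
HALLMARK_NAMES = (
    "proliferative_signalling",
    "evading_growth_suppressors",
    "resisting_cell_death",
    "replicative_immortality",
    "angiogenesis",
    "invasion_and_metastasis",
    "genome_instability",
    "tumour_promoting_inflammation",
    "deregulated_metabolism",
    "immune_evasion",
)

# Stage tags mixed into the seed so each generator draws an independent,
# reproducible stream.
_STAGE_NETWORK = 11
_STAGE_SETS = 23
_STAGE_EXPRESSION = 37
_STAGE_DEPENDENCY = 53


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Sizes default to a desk-scale genome of 500 genes across 3 lineages
    of 50 cell lines each; the planted signal puts unit effects on node
    degree and on the count of resisting-cell-death hallmark neighbors.
    ``noise_sd`` is the per-observation Gaussian noise used both in the
    expression scheme and in the per-(gene, cell line) score noise;
    ``gene_noise_sd`` adds per-(gene, lineage) score variation that does
    not average away across cell lines, emulating dependency variation
    the network features cannot explain.
    """

    n_genes: int = 500
    n_samples_per_lineage: int = 50
    n_lineages: int = 3
    attachment_edges: int = 2
    weight_low: float = 0.5
    weight_high: float = 3.0
    n_cgc: int = 20
    hallmark_sizes: Sequence[int] = (15,) * 10
    hub_bias: float = 1.0
    planted_features: Sequence[str] = ("degree", "resisting_cell_death")
    planted_effect_sizes: Sequence[float] = (1.0, 1.0)
    noise_sd: float = 0.5
    gene_noise_sd: float = 0.2
    dependency_fraction: float = 0.15
    path_mode: str = "raw"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_lineage <= 0 or self.n_lineages <= 0:
            raise ValueError("sizes must be positive")
        if self.n_genes < self.attachment_edges + 1:
            raise ValueError("n_genes must exceed attachment_edges")
        if not (0 < self.weight_low <= self.weight_high):
            raise ValueError("need 0 < weight_low <= weight_high")
        if self.n_cgc >= self.n_genes:
            raise ValueError("n_cgc must be smaller than n_genes")
        if len(self.hallmark_sizes) != 10:
            raise ValueError("hallmark_sizes must have exactly 10 entries")
        if self.n_cgc + sum(self.hallmark_sizes) > self.n_genes:
            raise ValueError("gene sets exceed the genome size")
        if len(self.planted_features) != len(self.planted_effect_sizes):
            raise ValueError("planted_features and planted_effect_sizes differ in length")
        if self.noise_sd < 0 or self.gene_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (0 < self.dependency_fraction < 1):
            raise ValueError("dependency_fraction must be in (0, 1)")

    def lineage_names(self) -> list[str]:
        return [f"lineage_{i + 1:02d}" for i in range(self.n_lineages)]


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, plus the planted ground truth."""

    config: SyntheticConfig
    network: nx.Graph
    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    features: FeatureTable
    scores: DependencyScores
    truth_labels: DependencyLabels
    truth_feature_weights: dict[str, float]


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_network(cfg: SyntheticConfig) -> nx.Graph:
    """Scale-free weighted gene network via preferential attachment.

    Yields a connected graph whose degree distribution is heavy-tailed
    (a few hubs, many low-degree genes), resembling inferred regulatory
    networks.  Edge weights are drawn uniformly from
    ``[weight_low, weight_high]`` as stand-ins for MI scores.
    """
    rng = np.random.default_rng([cfg.seed, _STAGE_NETWORK])
    g = nx.barabasi_albert_graph(cfg.n_genes, cfg.attachment_edges, seed=rng)
    names = _gene_names(cfg.n_genes)
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    weights = rng.uniform(cfg.weight_low, cfg.weight_high, g.number_of_edges())
    for (u, v), w in zip(sorted(g.edges), weights):
        g[u][v]["weight"] = float(w)
    return g


def generate_gene_sets(network: nx.Graph, cfg: SyntheticConfig) -> GeneSetCollection:
    """Disjoint CGC-like and hallmark-like gene sets.

    Sampling without replacement with probability proportional to
    ``degree ** hub_bias``; a bias of 0 gives a degree-agnostic null.
    The CGC set and the 10 hallmark sets are mutually disjoint so planted
    hallmark signals stay attributable.
    """
    rng = np.random.default_rng([cfg.seed, _STAGE_SETS])
    nodes = np.array(sorted(network.nodes))
    degrees = np.array([network.degree(g) for g in nodes], dtype=float)
    available = np.ones(len(nodes), dtype=bool)

    def _draw(size: int) -> list[str]:
        idx = np.flatnonzero(available)
        w = np.maximum(degrees[idx], 1.0) ** cfg.hub_bias
        chosen = rng.choice(idx, size=size, replace=False, p=w / w.sum())
        available[chosen] = False
        return [str(nodes[i]) for i in sorted(chosen)]

    cgc = _draw(cfg.n_cgc)
    hallmarks = {
        name: frozenset(_draw(size))
        for name, size in zip(HALLMARK_NAMES, cfg.hallmark_sizes)
    }
    tiers = {g: 1 + (i % 2) for i, g in enumerate(cgc)}
    return GeneSetCollection(hallmark_sets=hallmarks, cgc_genes=cgc, cgc_tiers=tiers)


def generate_expression(network: nx.Graph, cfg: SyntheticConfig) -> ExpressionMatrix:
    """Expression from a linear-Gaussian scheme over an acyclic orientation.

    Nodes are put in a random order and every edge is oriented from the
    earlier to the later endpoint, giving a DAG.  Each root gene is unit
    Gaussian; every other gene is a weight-proportional signed mix of its
    parents plus ``noise_sd`` Gaussian noise, so adjacent genes carry
    higher absolute correlation than non-adjacent pairs in expectation
    (and correlation magnitude approaches 1 as ``noise_sd`` approaches 0).
    Lineages share the structural coefficients and differ only in their
    sample draws.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    if cfg.n_samples_per_lineage < 3:
        raise ValueError("n_samples_per_lineage must be >= 3")
    rng = np.random.default_rng([cfg.seed, _STAGE_EXPRESSION])
    nodes = sorted(network.nodes)
    order = {g: r for r, g in enumerate(rng.permutation(nodes))}
    sign = {
        (u, v): float(rng.choice([-1.0, 1.0]))
        for u, v in sorted(network.edges)
    }

    topo = sorted(nodes, key=order.__getitem__)
    parents: dict[str, list[tuple[str, float]]] = {g: [] for g in nodes}
    for u, v in sorted(network.edges):
        child, parent = (u, v) if order[u] > order[v] else (v, u)
        w = network[u][v]["weight"] * sign[(u, v)]
        parents[child].append((parent, w))

    n_total = cfg.n_samples_per_lineage * cfg.n_lineages
    X = pd.DataFrame(0.0, index=nodes, columns=range(n_total))
    values = {g: np.zeros(n_total) for g in nodes}
    for g in topo:
        if not parents[g]:
            values[g] = rng.standard_normal(n_total)
        else:
            total_w = sum(abs(w) for _, w in parents[g])
            mix = sum((w / total_w) * values[p] for p, w in parents[g])
            values[g] = mix + cfg.noise_sd * rng.standard_normal(n_total)
    for g in nodes:
        X.loc[g] = values[g]

    sample_ids, lineage_of = [], {}
    for li, lineage in enumerate(cfg.lineage_names()):
        for j in range(cfg.n_samples_per_lineage):
            sid = f"{lineage}_C{j + 1:03d}"
            sample_ids.append(sid)
            lineage_of[sid] = lineage
    X.columns = sample_ids
    return ExpressionMatrix(values=X, lineage_of=lineage_of)


def _planted_signal(features: FeatureTable, cfg: SyntheticConfig) -> np.ndarray:
    """Z-scored linear combination of the planted feature columns."""
    by_name = {c[1]: c for c in features.data.columns}
    signal = np.zeros(len(features.data))
    for name, beta in zip(cfg.planted_features, cfg.planted_effect_sizes):
        if name not in by_name:
            raise KeyError(f"planted feature {name!r} absent from feature table")
        col = features.data[by_name[name]].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        signal += beta * z
    return signal


def generate_dependency(
    network: nx.Graph, features: FeatureTable, cfg: SyntheticConfig
) -> tuple[DependencyScores, DependencyLabels]:
    """Dependency scores as a noisy decreasing function of planted features.

    Per (gene, cell line) score: ``-(signal) - offset + eta + eps`` where
    ``signal`` is the z-scored planted combination, ``eta`` is
    per-(gene, lineage) noise (sd ``gene_noise_sd``), ``eps`` is
    per-observation noise (sd ``noise_sd``), and the offset is calibrated
    on the realized lineage means so the fraction of (gene, lineage)
    pairs at or below -1 matches ``dependency_fraction``.  The realized
    binary truth labels are returned alongside.
    """
    rng = np.random.default_rng([cfg.seed, _STAGE_DEPENDENCY])
    genes = features.gene_ids
    n_genes = len(genes)
    lineages = cfg.lineage_names()
    n_per = cfg.n_samples_per_lineage

    signal = _planted_signal(features, cfg)
    eta = cfg.gene_noise_sd * rng.standard_normal((n_genes, len(lineages)))
    eps = cfg.noise_sd * rng.standard_normal((n_genes, len(lineages) * n_per))

    # Pre-offset realized lineage means; the offset is the shift that puts
    # the requested fraction of (gene, lineage) means at or below -1.
    eps_lineage_mean = eps.reshape(n_genes, len(lineages), n_per).mean(axis=2)
    m0 = -signal[:, None] + eta + eps_lineage_mean
    offset = float(np.quantile(m0, cfg.dependency_fraction)) + 1.0

    raw = -signal[:, None, None] - offset + eta[:, :, None] + eps.reshape(
        n_genes, len(lineages), n_per
    )
    sample_ids, lineage_of = [], {}
    for lineage in lineages:
        for j in range(n_per):
            sid = f"{lineage}_C{j + 1:03d}"
            sample_ids.append(sid)
            lineage_of[sid] = lineage
    values = pd.DataFrame(
        raw.reshape(n_genes, -1), index=genes, columns=sample_ids
    )
    scores = DependencyScores(values=values, lineage_of=lineage_of)

    means = m0 - offset
    rows = []
    for li, lineage in enumerate(lineages):
        for gi, g in enumerate(genes):
            rows.append(
                {
                    "gene": g,
                    "lineage": lineage,
                    "mean_score": means[gi, li],
                    "label": int(means[gi, li] <= DEFAULT_CUTOFF),
                }
            )
    truth = DependencyLabels(pd.DataFrame(rows), cutoff_used=DEFAULT_CUTOFF)

    realized = truth.table["label"].mean()
    if abs(realized - cfg.dependency_fraction) > 0.05:
        logger.warning(
            "realized dependent fraction %.3f deviates from target %.3f",
            realized,
            cfg.dependency_fraction,
        )
    return scores, truth


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Run every generator stage and bundle the results with the truth."""
    network = generate_network(cfg)
    gene_sets = generate_gene_sets(network, cfg)
    expression = generate_expression(network, cfg)
    features = compute_network_features(network, gene_sets, path_mode=cfg.path_mode)
    scores, truth = generate_dependency(network, features, cfg)
    return SyntheticDataset(
        config=cfg,
        network=network,
        expression=expression,
        gene_sets=gene_sets,
        features=features,
        scores=scores,
        truth_labels=truth,
        truth_feature_weights=dict(
            zip(cfg.planted_features, map(float, cfg.planted_effect_sizes))
        ),
    )
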