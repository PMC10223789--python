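import networkx as nx
import numpy as np
import pytest

from depnet.synthetic import SyntheticConfig, generate_dataset

# Study conditions for recovery-style tests: desk-scale genome, planted
# effects on degree and one hallmark-neighbor count, per-observation score
# noise 0.25.
STUDY_KWARGS = dict(noise_sd=0.25)

# Small, fast variant for structural tests.
SMALL_KWARGS = dict(
    n_genes=150,
    n_samples_per_lineage=25,
    n_lineages=2,
    n_cgc=8,
    hallmark_sizes=(5,) * 10,
    noise_sd=0.25,
)


@pytest.fixture(scope="session")
def study_dataset():
    """Full-size synthetic dataset under the study conditions (seed 3)."""
    return generate_dataset(SyntheticConfig(seed=3, **STUDY_KWARGS))


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SyntheticConfig(seed=11, **SMALL_KWARGS))


@pytest.fixture(scope="session")
def separable_dataset():
    """Noise-free planted signal on node degree.

    With zero score noise every degree atom is labeled as a block, so the
    classes are separated by a real margin (a clean degree threshold)
    rather than a density-free quantile cut.
    """
    cfg = SyntheticConfig(
        n_genes=400,
        n_samples_per_lineage=25,
        n_lineages=2,
        n_cgc=10,
        hallmark_sizes=(8,) * 10,
        planted_features=("degree",),
        planted_effect_sizes=(3.0,),
        noise_sd=0.0,
        gene_noise_sd=0.0,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture
def triangle_net():
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 3.0), ("b", "c", 2.0), ("a", "c", 1.0)])
    return g


@pytest.fixture
def path_net():
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0)])
    return g


def random_weighted_graph(rng: np.random.Generator, n: int, p: float = 0.35) -> nx.Graph:
    """Erdos-Renyi graph with uniform positive weights (test helper)."""
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    nodes = list(g.nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j], weight=float(rng.uniform(0.2, 4.0)))
    return g
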