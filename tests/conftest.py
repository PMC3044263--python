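import networkx as nx
import numpy as np
import pytest

from pathfill.graph import effective_edge_weight
from pathfill.model import Gene, GeneCatalog, Params
from pathfill.pipeline import Analysis
from pathfill.simulate import FixtureSpec, generate


@pytest.fixture(scope="session")
def default_dataset():
    """The benchmark fixture: 5 reference genomes, 200-gene target genome,
    one planted 6-gene pathway, fully conserved operon."""
    return generate(FixtureSpec())


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    return Analysis.from_dataset(default_dataset)


@pytest.fixture
def params():
    return Params()


@pytest.fixture
def make_catalog():
    """Factory: {genome: [gene ids]} -> catalog with one contig per genome."""

    def _make(spec):
        genes = []
        for genome, ids in spec.items():
            for i, gid in enumerate(ids):
                start = 1 + i * 1000
                genes.append(Gene(genome, gid, "c1", start, start + 899, "+"))
        return GeneCatalog(genes)

    return _make


def brute_force_path_distance(graph, source, target, params):
    """Exhaustive minimum over all simple paths in the penalized metric.

    Independent oracle for the Dijkstra implementation; exponential, use on
    tiny graphs only.
    """
    best = None
    for path in nx.all_simple_paths(graph, source, target):
        d = sum(
            effective_edge_weight(
                graph[a][b]["kind"], graph[a][b]["weight"], params
            )
            for a, b in zip(path, path[1:])
        )
        if best is None or d < best:
            best = d
    return best


def random_reference_graph(rng, max_vertices=8, max_edges=14):
    """A random typed weighted graph for oracle comparisons."""
    n = int(rng.integers(2, max_vertices + 1))
    g = nx.Graph()
    vertices = [f"v{i}" for i in range(n)]
    g.add_nodes_from(vertices)
    n_edges = int(rng.integers(1, max_edges + 1))
    for _ in range(n_edges):
        i, j = rng.choice(n, size=2, replace=False)
        kind = "operon" if rng.random() < 0.5 else "similarity"
        g.add_edge(vertices[int(i)], vertices[int(j)], kind=kind,
                   weight=float(rng.uniform(0, 1)))
    return g


def run_path_oracle_trials(n_trials, seed, params=None):
    """Compare Dijkstra vs brute force on random graphs; returns
    (n_compared, max absolute disagreement)."""
    from pathfill.graph import penalized_shortest_path

    params = params or Params()
    rng = np.random.default_rng(seed)
    worst = 0.0
    compared = 0
    for _ in range(n_trials):
        g = random_reference_graph(rng)
        vertices = sorted(g.nodes)
        i, j = rng.choice(len(vertices), size=2, replace=False)
        s, t = vertices[int(i)], vertices[int(j)]
        expected = brute_force_path_distance(g, s, t, params)
        got = penalized_shortest_path(g, s, t, params)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            worst = max(worst, abs(got.distance - expected))
            compared += 1
    return compared, worst
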