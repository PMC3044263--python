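"""Cross-genome reference graph and penalized shortest-path distances.

The reference graph has one vertex per gene of the target and reference
genomes, operon edges between neighbouring genes of one genome (weight
1 - p_operon) and similarity edges between homologous genes of different
genomes (weight from the BLAST E-value). The distance of a path is

    D(path) = sum over operon edges of d_o
            + (norm / alpha) * sum over similarity edges of d_s
            + k * system_error,

where k is the edge count of the path: every inferred step costs a flat
reliability penalty on top of its evidence-based weight, so long chains of
individually plausible links are discounted. With alpha at its default of
380 (about 2 * norm) one similarity edge weighs roughly half an operon
edge. Because the penalty is folded into every edge's effective weight,
Dijkstra's algorithm is exact and minimizing paths are simple.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .distances import homology_distance, operon_distance, symmetrized_evalue
from .model import (
    GeneCatalog,
    HomologyHit,
    OperonPair,
    Params,
    ValidationError,
)

OPERON = "operon"
SIMILARITY = "similarity"

_UNREACHABLE = float("inf")


@dataclass(frozen=True)
class PenalizedPath:
    """A minimal-distance witness path between two genes."""

    source: str
    target: str
    vertices: tuple
    edges: tuple  # of (gene_a, gene_b, kind, weight)
    distance: float

    @property
    def k(self) -> int:
        return len(self.edges)


class LinkageGraph:
    """Per-seed lists of the K nearest target-genome genes.

    For each seed gene the single-source penalized shortest-path distances
    to all other target-genome genes are computed and only the K nearest
    candidates are retained; a candidate outside every seed's list has no
    defined path distance to the seed set.
    """

    def __init__(self, target_genome: str, K: int,
                 top: Mapping[str, Sequence], paths: Mapping[str, Mapping]):
        self.target_genome = target_genome
        self.K = K
        self._top = {s: tuple(v) for s, v in top.items()}
        self._paths = paths
        self._lookup = {
            s: {gene: dist for gene, dist in v} for s, v in self._top.items()
        }

    @property
    def seeds(self) -> list:
        return sorted(self._top)

    def top(self, seed: str) -> tuple:
        """(gene, distance) pairs retained for a seed, nearest first."""
        try:
            return self._top[seed]
        except KeyError:
            raise ValidationError(f"gene {seed!r} is not a seed") from None

    def distance(self, seed: str, gene: str) -> Optional[float]:
        """Retained distance from seed to gene, or None if outside the top-K."""
        self.top(seed)
        return self._lookup[seed].get(gene)

    def witness(self, seed: str, gene: str) -> Optional[PenalizedPath]:
        return self._paths.get(seed, {}).get(gene)

    def candidates(self) -> set:
        """Union of all retained candidate genes across seeds."""
        out: set = set()
        for entries in self._top.values():
            out.update(gene for gene, _ in entries)
        return out


def build_reference_graph(
    catalog: GeneCatalog,
    operon_pairs: Iterable[OperonPair],
    homology_hits: Iterable[HomologyHit],
    params: Params,
) -> nx.Graph:
    """Assemble the typed, weighted reference graph over all genes.

    Operon edges connect neighbouring genes of one genome; similarity edges
    connect genes of different genomes whose symmetrized (minimum over both
    directions) E-value passes the cutoff. Intra-genome homology produces no
    edge. Every gene is a vertex even if isolated.
    """
    g = nx.Graph()
    for gene in catalog:
        g.add_node(gene.gene_id, genome=gene.genome_id)

    for pair in operon_pairs:
        for gid in (pair.gene_a, pair.gene_b):
            if catalog.genome_of(gid) != pair.genome_id:
                raise ValidationError(
                    f"operon pair {pair.gene_a}/{pair.gene_b}: gene {gid} is "
                    f"not in genome {pair.genome_id}"
                )
        g.add_edge(
            pair.gene_a,
            pair.gene_b,
            kind=OPERON,
            weight=operon_distance(pair.prob),
        )

    best_e: dict[frozenset, float] = {}
    for hit in homology_hits:
        if catalog.genome_of(hit.query_gene) == catalog.genome_of(hit.subject_gene):
            continue  # paralogs and intra-genome hits carry no edge
        key = frozenset((hit.query_gene, hit.subject_gene))
        cur = best_e.get(key)
        best_e[key] = hit.evalue if cur is None else symmetrized_evalue(cur, hit.evalue)

    for key, evalue in best_e.items():
        if evalue > params.edge_evalue_cutoff:
            continue
        a, b = sorted(key)
        if g.has_edge(a, b):  # operon evidence wins; cannot happen cross-genome
            continue
        g.add_edge(a, b, kind=SIMILARITY,
                   weight=homology_distance(evalue, params.norm))
    return g


def effective_edge_weight(kind: str, weight: float, params: Params) -> float:
    """Edge weight in the penalized path metric (penalty included).

    Similarity edges are scaled by norm/alpha (alpha_scope='similarity');
    with alpha_scope='all' both edge types are scaled. alpha=0 makes scaled
    edges unusable (infinite weight).
    """
    scaled = params.alpha_scope == "all" or kind == SIMILARITY
    if scaled:
        if params.alpha == 0:
            return _UNREACHABLE
        weight = weight * params.norm / params.alpha
    return weight + params.system_error


def _single_source(
    graph: nx.Graph, source: str, params: Params
) -> dict[str, tuple[float, tuple]]:
    """Deterministic Dijkstra from one source over effective edge weights.

    Returns {vertex: (distance, vertex path)}. Ties in distance are broken
    by fewer edges, then by the lexicographically smallest vertex sequence,
    so witness paths are reproducible across runs and platforms.
    """
    if source not in graph:
        raise ValidationError(f"unknown gene {source!r}")
    best: dict[str, tuple[float, int, tuple]] = {}
    heap: list[tuple[float, int, tuple]] = [(0.0, 0, (source,))]
    while heap:
        dist, k, path = heapq.heappop(heap)
        u = path[-1]
        if u in best:
            continue
        best[u] = (dist, k, path)
        for v, data in graph[u].items():
            if v in best:
                continue
            w = effective_edge_weight(data["kind"], data["weight"], params)
            if w == _UNREACHABLE:
                continue
            heapq.heappush(heap, (dist + w, k + 1, path + (v,)))
    return {v: (d, p) for v, (d, k, p) in best.items()}


def _materialize(graph: nx.Graph, path: tuple) -> tuple:
    edges = []
    for a, b in zip(path, path[1:]):
        data = graph[a][b]
        edges.append((a, b, data["kind"], data["weight"]))
    return tuple(edges)


def penalized_shortest_path(
    graph: nx.Graph, source: str, target: str, params: Params
) -> Optional[PenalizedPath]:
    """Minimal penalized-distance path between two genes, or None.

    Exact because every effective edge weight is non-negative
    (>= system_error). Undefined (None) when the genes are disconnected.
    """
    if source == target:
        raise ValidationError("source and target must differ")
    for gid in (source, target):
        if gid not in graph:
            raise ValidationError(f"unknown gene {gid!r}")
    reach = _single_source(graph, source, params)
    if target not in reach:
        return None
    dist, path = reach[target]
    return PenalizedPath(source, target, path, _materialize(graph, path), dist)


def build_linkage_graph(
    graph: nx.Graph,
    catalog: GeneCatalog,
    target_genome: str,
    seeds: Iterable[str],
    params: Params,
    keep_witnesses: bool = True,
) -> LinkageGraph:
    """Per-seed top-K nearest target-genome genes by penalized path distance.

    Only rows for the given seeds are materialized; the seed itself is never
    its own candidate. Ties at the K-th distance are broken by gene id.
    """
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValidationError("empty seed set")
    target_ids = set(catalog.gene_ids_of(target_genome))
    for s in seeds:
        if s not in target_ids:
            raise ValidationError(
                f"seed {s!r} is not a gene of target genome {target_genome}"
            )
    top: dict[str, list] = {}
    paths: dict[str, dict] = {}
    for seed in seeds:
        reach = _single_source(graph, seed, params)
        entries = sorted(
            (
                (dist, gene)
                for gene, (dist, _p) in reach.items()
                if gene != seed and gene in target_ids
            ),
        )[: params.K]
        top[seed] = [(gene, dist) for dist, gene in entries]
        if keep_witnesses:
            paths[seed] = {
                gene: PenalizedPath(
                    seed, gene, reach[gene][1],
                    _materialize(graph, reach[gene][1]), dist,
                )
                for gene, dist in top[seed]
            }
    return LinkageGraph(target_genome, params.K, top, paths)


def export_edge_list(graph: nx.Graph, path) -> None:
    """3-column edge list (source, target, weight) plus the edge type."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("source\ttarget\tweight\tedge_type\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['weight']!r}\t{data['kind']}\n")


def export_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
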