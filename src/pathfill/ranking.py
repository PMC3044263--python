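"""Pathway-to-gene distance fusion and candidate ranking.

A pathway's known genes G(P) act as seeds. For every candidate gene the
per-seed path distances (restricted to each seed's K-nearest list) and
per-seed profile distances (restricted to each seed's K_phylo-nearest list)
are aggregated over all |G(P)| seeds, fused as

    D(P, x) = (D_path + beta * D_phylo) / T,

where T counts the defined terms, and the top gamma candidates by fused
distance are output. A candidate outside every seed's top list for an
evidence type has that distance undefined; a seed whose list omits the
candidate contributes an imputed cap (one maximal-weight penalized edge)
under the default mean aggregator, so candidates close to many seeds are
rewarded.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import networkx as nx

from .graph import LinkageGraph
from .model import Params, Pathway, RankedCandidate, ValidationError
from .profiles import ProfileSet


def _aggregate_over_seeds(
    per_seed: dict[str, Optional[float]], params: Params
) -> Optional[float]:
    """Aggregate per-seed distances; None when no seed retains the candidate."""
    defined = [d for d in per_seed.values() if d is not None]
    if not defined:
        return None
    if params.aggregator == "min":
        return min(defined)
    cap = params.absent_seed_cap
    total = sum(d if d is not None else cap for d in per_seed.values())
    return total / len(per_seed)


def pathway_path_distance(
    pathway: Pathway, candidate: str, linkage: LinkageGraph, params: Params
) -> Optional[float]:
    """Seed-set path distance of a candidate, or None if never retained."""
    if candidate in pathway.genes:
        raise ValidationError(
            f"candidate {candidate} is already a member of "
            f"pathway {pathway.pathway_id}"
        )
    per_seed = {s: linkage.distance(s, candidate) for s in pathway.genes}
    return _aggregate_over_seeds(per_seed, params)


def pathway_phylo_distance(
    pathway: Pathway,
    candidate: str,
    phylo_top: dict,
    params: Params,
) -> Optional[float]:
    """Seed-set profile distance; phylo_top maps seed -> {gene: distance}."""
    if candidate in pathway.genes:
        raise ValidationError(
            f"candidate {candidate} is already a member of "
            f"pathway {pathway.pathway_id}"
        )
    per_seed = {s: phylo_top[s].get(candidate) for s in pathway.genes}
    return _aggregate_over_seeds(per_seed, params)


def combined_distance(
    d_path: Optional[float], d_phylo: Optional[float], beta: float
) -> tuple[float, int]:
    """Fused distance (d_path + beta*d_phylo)/T with undefined terms dropped."""
    terms = []
    if d_path is not None:
        terms.append(d_path)
    if d_phylo is not None:
        terms.append(beta * d_phylo)
    if not terms:
        raise ValidationError("both distances undefined")
    return sum(terms) / len(terms), len(terms)


def phylo_top_lists(
    pathway_genes: Iterable[str], profiles: ProfileSet, params: Params
) -> dict:
    """Per-seed K_phylo-nearest lookup tables, seeds without a profile empty."""
    out = {}
    for seed in pathway_genes:
        if seed in profiles:
            out[seed] = dict(profiles.topk(seed, params))
        else:
            out[seed] = {}
    return out


def rank_candidates(
    pathway: Pathway,
    linkage: LinkageGraph,
    profiles: Optional[ProfileSet],
    params: Params,
    phylo_top: Optional[dict] = None,
) -> list[RankedCandidate]:
    """Top-gamma candidate genes of a pathway by fused distance.

    Candidates are target-genome genes outside G(P) with at least one
    defined distance; sorted ascending by fused distance, ties broken by
    more evidence types (T descending) then gene id; truncated to gamma.
    Passing profiles=None ranks on the path distance alone; a precomputed
    phylo_top table (seed -> {gene: distance}) overrides profiles.
    """
    if not pathway.genes:
        raise ValidationError("empty pathway")
    if phylo_top is None:
        phylo_top = (
            phylo_top_lists(pathway.genes, profiles, params)
            if profiles is not None
            else {s: {} for s in pathway.genes}
        )
    candidates: set = set(linkage.candidates())
    for table in phylo_top.values():
        candidates.update(table)
    candidates -= pathway.genes

    scored = []
    for gene in candidates:
        d_path = pathway_path_distance(pathway, gene, linkage, params)
        d_phylo = pathway_phylo_distance(pathway, gene, phylo_top, params)
        if d_path is None and d_phylo is None:
            continue
        combined, T = combined_distance(d_path, d_phylo, params.beta)
        scored.append((combined, -T, gene, d_path, d_phylo, T))
    scored.sort()

    out = []
    for rank, (combined, _negT, gene, d_path, d_phylo, T) in enumerate(
        scored[: params.gamma], start=1
    ):
        out.append(
            RankedCandidate(
                pathway.pathway_id, gene, d_path, d_phylo, combined, T, rank
            )
        )
    return out


def recall_graph(
    pathway: Pathway,
    rank_fn: Callable[[frozenset], Sequence[RankedCandidate]],
    params: Params,
) -> nx.Graph:
    """Mutual-recall graph over a pathway's genes.

    For each ordered pair (a, b) of pathway genes, the ranking is run with
    {a} alone as the seed set; an undirected edge (a, b) is added when b
    appears in the top-gamma output. Connected components of the result are
    the pathway's candidate functional modules.
    """
    g = nx.Graph()
    g.add_nodes_from(pathway.genes)
    for a in sorted(pathway.genes):
        ranked = rank_fn(frozenset([a]))
        recalled = {c.gene for c in ranked}
        for b in pathway.genes:
            if b != a and b in recalled:
                g.add_edge(a, b)
    return g


def recall_components(g: nx.Graph) -> list:
    """Connected components as sorted gene lists, largest first."""
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c))
    return comps
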