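"""End-to-end orchestration: cached analysis engine and the run pipeline.

`Analysis` bundles a loaded dataset (gene catalog, homology hits, operon
pairs, the target genome and the reference panel) and exposes ranking and
evaluation entry points. Reference graphs, profiles and per-seed top lists
are cached per parameter signature, so leave-one-out loops, cross-validation
grids and robustness sweeps reuse shared work.

`run_pipeline` executes the stage sequence (simulate or load inputs, build
graph, build profiles, rank every pathway, leave-one-out evaluation) and
writes a manifest with content hashes so reruns are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from . import io as pfio
from .evaluation import EvalReport, evaluate_pathways
from .graph import (
    LinkageGraph,
    build_reference_graph,
    export_edge_list,
    export_graphml,
)
from .model import GeneCatalog, Params, Pathway, RankedCandidate, ValidationError
from .profiles import ProfileSet, build_profiles
from .ranking import rank_candidates, recall_components, recall_graph
from .simulate import FixtureSpec, SyntheticDataset, generate


def _graph_key(params: Params) -> tuple:
    return (params.edge_evalue_cutoff, params.norm)

def _path_key(params: Params) -> tuple:
    return _graph_key(params) + (
        params.alpha, params.alpha_scope, params.system_error, params.K,
    )

def _phylo_key(params: Params) -> tuple:
    return (params.profile_evalue_cutoff, params.K_phylo,
            params.common_mode, params.entropy_floor)


class Analysis:
    """Ranking and evaluation over one loaded dataset."""

    def __init__(
        self,
        catalog: GeneCatalog,
        hits: Sequence,
        operon_pairs: Sequence,
        target_genome: str,
        reference_genomes: Sequence[str],
        pathways: Optional[Sequence[Pathway]] = None,
    ):
        if target_genome not in catalog.genomes:
            raise ValidationError(f"unknown target genome {target_genome!r}")
        self.catalog = catalog
        self.hits = list(hits)
        self.operon_pairs = list(operon_pairs)
        self.target_genome = target_genome
        self.reference_genomes = tuple(reference_genomes)
        self.pathways = list(pathways or [])
        self.n_target_genes = len(catalog.gene_ids_of(target_genome))
        self._graphs: dict = {}
        self._profiles: dict = {}
        self._seed_top: dict = {}
        self._seed_phylo: dict = {}

    @classmethod
    def from_dataset(cls, ds: SyntheticDataset) -> "Analysis":
        return cls(ds.catalog, ds.hits, ds.operon_pairs, ds.target_genome,
                   ds.reference_genomes, ds.pathways)

    def reference_graph(self, params: Params):
        key = _graph_key(params)
        if key not in self._graphs:
            self._graphs[key] = build_reference_graph(
                self.catalog, self.operon_pairs, self.hits, params
            )
        return self._graphs[key]

    def profiles(self, params: Params) -> ProfileSet:
        key = params.profile_evalue_cutoff
        if key not in self._profiles:
            self._profiles[key] = build_profiles(
                self.hits, self.catalog, self.target_genome,
                self.reference_genomes, cutoff=key,
            )
        return self._profiles[key]

    def linkage(self, seeds: Iterable[str], params: Params) -> LinkageGraph:
        """Linkage rows for a seed set, assembled from per-seed caches."""
        from .graph import build_linkage_graph

        seeds = sorted(set(seeds))
        key = _path_key(params)
        top: dict = {}
        paths: dict = {}
        for s in seeds:
            cached = self._seed_top.get((key, s))
            if cached is None:
                lg = build_linkage_graph(
                    self.reference_graph(params), self.catalog,
                    self.target_genome, [s], params,
                )
                cached = (lg.top(s), {g: lg.witness(s, g) for g, _ in lg.top(s)})
                self._seed_top[(key, s)] = cached
            top[s], paths[s] = cached
        return LinkageGraph(self.target_genome, params.K, top, paths)

    def phylo_top(self, seeds: Iterable[str], params: Params) -> dict:
        key = _phylo_key(params)
        prof = self.profiles(params)
        out = {}
        for s in sorted(set(seeds)):
            cached = self._seed_phylo.get((key, s))
            if cached is None:
                cached = dict(prof.topk(s, params)) if s in prof else {}
                self._seed_phylo[(key, s)] = cached
            out[s] = cached
        return out

    def rank(
        self,
        seeds: Iterable[str],
        params: Params,
        pathway_id: str = "query",
        use_profiles: bool = True,
    ) -> list[RankedCandidate]:
        """Top-gamma candidates for an arbitrary seed set."""
        pw = Pathway(pathway_id, frozenset(seeds))
        linkage = self.linkage(pw.genes, params)
        phylo_top = (
            self.phylo_top(pw.genes, params)
            if use_profiles
            else {s: {} for s in pw.genes}
        )
        return rank_candidates(pw, linkage, None, params, phylo_top=phylo_top)

    def rank_fn(self, use_profiles: bool = True):
        """Adapter with the evaluation-protocol signature (seeds, params)."""
        def fn(seeds: frozenset, params: Params):
            return self.rank(seeds, params, use_profiles=use_profiles)
        return fn

    def evaluate(self, params: Params, use_profiles: bool = True,
                 pathways: Optional[Sequence[Pathway]] = None) -> EvalReport:
        return evaluate_pathways(
            pathways if pathways is not None else self.pathways,
            self.rank_fn(use_profiles), params, self.n_target_genes,
        )

    def modules(self, pathway: Pathway, params: Params) -> list:
        """Recall-graph connected components of a pathway's genes."""
        g = recall_graph(
            pathway,
            lambda seeds: self.rank(seeds, params,
                                    pathway_id=pathway.pathway_id),
            params,
        )
        return recall_components(g)


def load_inputs(
    genes_path, hits_path, operons_path, genomes_path,
    pathways_path=None,
) -> Analysis:
    """Load the TSV input set; the reference panel is one genome per genus."""
    catalog = pfio.read_gene_table(genes_path)
    metas = pfio.read_genome_metadata(genomes_path)
    target = next(m.genome_id for m in metas if m.is_target)
    refs = pfio.select_reference_genomes(metas)
    hits = pfio.read_blast_tabular(hits_path)
    pairs = pfio.read_operon_pairs(operons_path, catalog)
    pathways = (
        pfio.read_pathways(pathways_path, catalog, target)
        if pathways_path
        else []
    )
    return Analysis(catalog, hits, pairs, target, refs, pathways)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def params_from_mapping(mapping: Optional[Mapping]) -> Params:
    return Params(**dict(mapping or {}))


def run_pipeline(config: Mapping, outdir, seed: Optional[int] = None) -> dict:
    """Execute the full stage sequence from a config mapping.

    Config keys: either `simulate` (FixtureSpec fields) or `inputs`
    ({genes, hits, operons, genomes, pathways} paths); optional `params`
    (Params fields) and `seed`. Outputs and a manifest (config echo, seed,
    per-stage output hashes — no timestamps, so reruns are byte-identical)
    are written under `outdir`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params_from_mapping(config.get("params"))
    if seed is None:
        seed = int(config.get("seed", 0))
    stages: list[dict] = []

    def record(stage: str, paths: Mapping[str, Path]) -> None:
        stages.append({
            "stage": stage,
            "outputs": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in sorted(paths.items())
            },
        })

    if "simulate" in config:
        spec = FixtureSpec(**{**config["simulate"], "seed": seed})
        ds = generate(spec)
        sim_dir = outdir / "inputs"
        paths = ds.write(sim_dir)
        record("simulate", paths)
        analysis = Analysis.from_dataset(ds)
    elif "inputs" in config:
        inp = config["inputs"]
        analysis = load_inputs(
            inp["genes"], inp["hits"], inp["operons"], inp["genomes"],
            inp.get("pathways"),
        )
        record("load", {})
    else:
        raise ValidationError("config needs a 'simulate' or 'inputs' section")

    graph = analysis.reference_graph(params)
    graph_paths = {
        "edges": outdir / "reference_graph.tsv",
        "graphml": outdir / "reference_graph.graphml",
    }
    export_edge_list(graph, graph_paths["edges"])
    export_graphml(graph, graph_paths["graphml"])
    record("build-graph", graph_paths)

    prof = analysis.profiles(params)
    prof_path = outdir / "profiles.tsv"
    prof.to_tsv(prof_path)
    record("profiles", {"profiles": prof_path})

    ranked: list[RankedCandidate] = []
    for pw in analysis.pathways:
        ranked.extend(analysis.rank(pw.genes, params, pathway_id=pw.pathway_id))
    rank_path = outdir / "rankings.tsv"
    pfio.write_rankings(ranked, rank_path)
    record("rank", {"rankings": rank_path})

    evaluable = [p for p in analysis.pathways if p.size >= 2]
    eval_paths: dict = {}
    if evaluable:
        report = analysis.evaluate(params)
        eval_paths["report"] = outdir / "evaluation.tsv"
        with open(eval_paths["report"], "w", encoding="utf-8") as fh:
            fh.write("pathway_id\tTP\tFP\tTN\tFN\tSE\tSP\tPPV\n")
            for pid in sorted(report.per_pathway):
                r = report.per_pathway[pid]
                c = r.counts

                def fmt(v):
                    return "" if v is None else repr(v)

                fh.write(
                    f"{pid}\t{c.TP}\t{c.FP}\t{c.TN}\t{c.FN}\t"
                    f"{fmt(r.SE)}\t{fmt(r.SP)}\t{fmt(r.PPV)}\n"
                )
        eval_paths["summary"] = outdir / "evaluation.json"
        with open(eval_paths["summary"], "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "seed": seed,
                    "params": dataclasses.asdict(params),
                    "N": report.N,
                    "SE_avg": report.SE_avg,
                    "SP_avg": report.SP_avg,
                    "PPV_avg": report.PPV_avg,
                    "metric_definitions": {
                        "TP": "held-out pathway genes recovered in the top-gamma",
                        "FP": "distinct non-pathway genes in any top-gamma "
                              "output of the pathway's leave-one-out runs",
                        "TN": "remaining target-genome genes",
                        "FN": "held-out pathway genes not recovered",
                    },
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        record("loo", eval_paths)

    manifest = {
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "stages": stages,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
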