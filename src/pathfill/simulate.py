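"""Seeded generator of synthetic multi-genome datasets with planted signal.

The generator emulates the data regime the method consumes: one target
genome plus a panel of reference genomes (one per genus), per-genome gene
tables, all-vs-all homology hits with E-values, operon-pair probabilities
for neighbouring genes, and pathway membership lists.

The planted structure realizes the topology the method exploits: each
planted pathway is a set of genes *scattered* around the target genome
whose orthologs sit side by side in an operon in a fraction
(operon_conservation) of the reference genomes. A seed gene then reaches a
fellow pathway gene through a similarity edge into a conserved genome, a
short chain of high-probability operon edges, and a similarity edge back —
exactly the multi-step association the penalized path distance scores.
operon_conservation also governs ortholog presence: at 0 the planted genes
are target-specific (no homologs anywhere), so neither path nor profile
evidence exists and recovery collapses; this is the negative control.

Everything is deterministic given the seed; no sequence content is
generated because the method consumes only hits and probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import io as pfio
from .evaluation import ConfusionCounts
from .model import (
    Gene,
    GeneCatalog,
    GenomeMeta,
    HomologyHit,
    OperonPair,
    Pathway,
    ValidationError,
)

GENE_SPACING = 1000  # bp between gene starts; only order matters downstream
GENE_LENGTH = 900


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of a synthetic dataset.

    Defaults describe the benchmark condition: 5 reference genomes, a
    200-gene target genome, one planted 6-gene pathway whose operon is
    conserved in every reference genome, moderate background profile
    density, and a sprinkle of above-cutoff noise hits.
    """

    n_reference_genomes: int = 5
    genes_per_genome: int = 200
    n_planted_pathways: int = 1
    operon_size_range: tuple = (6, 6)
    operon_conservation: float = 1.0
    #: planted pathways use disjoint conserved-genome subsets (needs
    #: n_planted_pathways * conserved count <= n_reference_genomes)
    disjoint_conservation: bool = False
    #: ortholog E-values are 10**(-u) with u uniform in this range
    ortholog_exponent_range: tuple = (30.0, 185.0)
    #: background homolog E-values are 10**(-u) with u uniform in this range
    background_exponent_range: tuple = (5.0, 30.0)
    #: per reference genome, probability a background target gene has a homolog
    background_presence: float = 0.3
    #: above-cutoff noise hits per gene of the dataset
    noise_edge_rate: float = 0.02
    background_operon_prob_range: tuple = (0.0, 0.2)
    planted_operon_prob_range: tuple = (0.9, 0.999)
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_reference_genomes, self.genes_per_genome,
               self.n_planted_pathways) <= 0:
            raise ValidationError("all counts must be positive")
        if not 0.0 <= self.operon_conservation <= 1.0:
            raise ValidationError("operon_conservation must be in [0, 1]")
        if not 0.0 <= self.background_presence <= 1.0:
            raise ValidationError("background_presence must be in [0, 1]")
        lo, hi = self.operon_size_range
        if lo < 2 or hi < lo:
            raise ValidationError("operon_size_range must be (lo, hi), lo >= 2")
        if hi > self.genes_per_genome // 2:
            raise ValidationError(
                "planted operon larger than half a genome cannot be placed"
            )


@dataclass(frozen=True)
class FixtureTruth:
    """Planted structure, sufficient to score any prediction."""

    target_genome: str
    reference_genomes: tuple
    pathways: Mapping[str, frozenset]
    #: pathway -> tuple of conserved reference genome ids
    conserved_genomes: Mapping[str, tuple]
    #: (pathway, target gene) -> {reference genome: ortholog gene}
    orthologs: Mapping[tuple, Mapping[str, str]]
    #: (pathway, reference genome) -> ordered run of ortholog gene ids
    operon_runs: Mapping[tuple, tuple]
    target_gene_ids: frozenset


@dataclass
class SyntheticDataset:
    spec: FixtureSpec
    catalog: GeneCatalog
    metas: list
    hits: list
    operon_pairs: list
    pathways: list
    truth: FixtureTruth

    @property
    def target_genome(self) -> str:
        return self.truth.target_genome

    @property
    def reference_genomes(self) -> tuple:
        return self.truth.reference_genomes

    @property
    def n_target_genes(self) -> int:
        return len(self.truth.target_gene_ids)

    def write(self, outdir) -> dict:
        """Emit every input format as TSV; returns {name: path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.tsv",
            "hits": outdir / "hits.blast6",
            "operons": outdir / "operon_pairs.tsv",
            "pathways": outdir / "pathways.tsv",
            "genomes": outdir / "genomes.tsv",
            "truth": outdir / "truth_memberships.tsv",
        }
        pfio.write_gene_table(self.catalog, paths["genes"])
        pfio.write_blast_tabular(self.hits, paths["hits"])
        pfio.write_operon_pairs(self.operon_pairs, paths["operons"])
        pfio.write_pathways(self.pathways, paths["pathways"])
        pfio.write_genome_metadata(self.metas, paths["genomes"])
        pfio.write_pathways(
            [Pathway(pid, genes) for pid, genes in sorted(self.truth.pathways.items())],
            paths["truth"],
        )
        return paths


def _gene_id(genome: str, index: int) -> str:
    return f"{genome}_g{index:04d}"


def _scatter_indices(rng, n_genes: int, size: int, used: set,
                     min_gap: int = 3) -> list:
    """Pick `size` well-separated target gene indices avoiding `used`."""
    chosen: list = []
    candidates = rng.permutation(n_genes)
    for i in candidates:
        i = int(i)
        if any(abs(i - u) < min_gap for u in used) or any(
            abs(i - c) < min_gap for c in chosen
        ):
            continue
        chosen.append(i)
        if len(chosen) == size:
            return sorted(chosen)
    raise ValidationError(
        "could not scatter planted genes: genome too small for the requested "
        "pathways"
    )


def _place_run(rng, n_genes: int, size: int, used: set, gap: int = 2) -> int:
    """Start index of a fresh adjacent run, leaving a gap around used runs."""
    starts = rng.permutation(n_genes - size + 1)
    for s in starts:
        s = int(s)
        if not any(s - gap <= u <= s + size - 1 + gap for u in used):
            return s
    raise ValidationError("could not place a planted operon run")


def generate(spec: FixtureSpec) -> SyntheticDataset:
    """Build a synthetic dataset with planted pathways; deterministic by seed."""
    rng = np.random.default_rng(spec.seed)
    target = "T000"
    refs = tuple(f"R{i + 1:03d}" for i in range(spec.n_reference_genomes))
    genomes = (target,) + refs
    n = spec.genes_per_genome

    genes = []
    for genome in genomes:
        strands = rng.choice(["+", "-"], size=n)
        for i in range(n):
            start = 1 + i * GENE_SPACING
            genes.append(
                Gene(genome, _gene_id(genome, i), "c1", start,
                     start + GENE_LENGTH - 1, str(strands[i]))
            )
    catalog = GeneCatalog(genes)

    metas = [GenomeMeta(target, "Targetus", n * GENE_SPACING + 500, True)]
    metas += [
        GenomeMeta(g, f"Genus{i + 1:03d}", n * GENE_SPACING + 500, False)
        for i, g in enumerate(refs)
    ]

    # background operon probabilities for every neighbouring pair
    lo_p, hi_p = spec.background_operon_prob_range
    pair_prob: dict[tuple, float] = {}
    for genome in genomes:
        ids = catalog.gene_ids_of(genome)
        probs = rng.uniform(lo_p, hi_p, size=len(ids) - 1)
        for j, (a, b) in enumerate(zip(ids, ids[1:])):
            pair_prob[(genome, a, b)] = float(probs[j])

    n_cons = int(round(spec.operon_conservation * spec.n_reference_genomes))
    if spec.disjoint_conservation and n_cons * spec.n_planted_pathways > len(refs):
        raise ValidationError(
            "disjoint conservation needs enough reference genomes for every "
            "pathway's conserved subset"
        )

    hits: list = []
    pathways: list = []
    truth_pathways: dict = {}
    truth_conserved: dict = {}
    truth_orthologs: dict = {}
    truth_runs: dict = {}
    used_target: set = set()
    used_ref: dict[str, set] = {g: set() for g in refs}
    available_refs = list(refs)

    u_lo, u_hi = spec.ortholog_exponent_range
    lo_pp, hi_pp = spec.planted_operon_prob_range
    for p in range(spec.n_planted_pathways):
        pid = f"pw{p + 1:04d}"
        size = int(rng.integers(spec.operon_size_range[0],
                                spec.operon_size_range[1] + 1))
        member_idx = _scatter_indices(rng, n, size, used_target)
        used_target.update(member_idx)
        members = [_gene_id(target, i) for i in member_idx]
        truth_pathways[pid] = frozenset(members)
        pathways.append(Pathway(pid, frozenset(members)))

        if spec.disjoint_conservation:
            pick = rng.choice(len(available_refs), size=n_cons, replace=False)
            conserved = tuple(sorted(available_refs[i] for i in pick))
            available_refs = [g for g in available_refs if g not in conserved]
        else:
            pick = rng.choice(len(refs), size=n_cons, replace=False)
            conserved = tuple(sorted(refs[i] for i in pick))
        truth_conserved[pid] = conserved

        for genome in conserved:
            start = _place_run(rng, n, size, used_ref[genome])
            run_idx = list(range(start, start + size))
            used_ref[genome].update(run_idx)
            run = tuple(_gene_id(genome, i) for i in run_idx)
            truth_runs[(pid, genome)] = run
            for member, ortholog in zip(members, run):
                u = float(rng.uniform(u_lo, u_hi))
                e = 10.0 ** (-u)
                hits.append(HomologyHit(member, ortholog, e))
                hits.append(HomologyHit(ortholog, member, e))
                truth_orthologs.setdefault((pid, member), {})[genome] = ortholog
            probs = rng.uniform(lo_pp, hi_pp, size=size - 1)
            for j, (a, b) in enumerate(zip(run, run[1:])):
                pair_prob[(genome, a, b)] = float(probs[j])

    # background homologs: profile signal for non-planted target genes,
    # pointed away from planted runs so they do not shortcut the structure
    b_lo, b_hi = spec.background_exponent_range
    target_ids = catalog.gene_ids_of(target)
    planted = set().union(*truth_pathways.values()) if truth_pathways else set()
    for i, gid in enumerate(target_ids):
        if gid in planted:
            continue
        for genome in refs:
            if rng.random() >= spec.background_presence:
                continue
            free = [j for j in range(n) if j not in used_ref[genome]]
            j = int(rng.choice(free))
            e = 10.0 ** (-float(rng.uniform(b_lo, b_hi)))
            hits.append(HomologyHit(gid, _gene_id(genome, j), e))

    # above-cutoff noise hits: exercise the E-value cutoff filter
    n_noise = int(round(spec.noise_edge_rate * len(genomes) * n))
    for _ in range(n_noise):
        ga, gb = rng.choice(len(genomes), size=2, replace=False)
        ia, ib = rng.integers(0, n, size=2)
        e = 10.0 ** (-float(rng.uniform(-1.0, 2.0)))  # E in [0.01, 10]
        hits.append(
            HomologyHit(
                _gene_id(genomes[ga], int(ia)),
                _gene_id(genomes[gb], int(ib)),
                max(e, 0.01),
            )
        )

    # a few strong intra-genome hits: paralogs, must not create edges
    for _ in range(2):
        ia, ib = rng.choice(n, size=2, replace=False)
        hits.append(
            HomologyHit(
                _gene_id(target, int(ia)), _gene_id(target, int(ib)), 1e-40
            )
        )

    operon_pairs = [
        OperonPair(genome, a, b, prob)
        for (genome, a, b), prob in sorted(pair_prob.items())
    ]
    truth = FixtureTruth(
        target_genome=target,
        reference_genomes=refs,
        pathways=truth_pathways,
        conserved_genomes=truth_conserved,
        orthologs=truth_orthologs,
        operon_runs=truth_runs,
        target_gene_ids=frozenset(target_ids),
    )
    return SyntheticDataset(spec, catalog, metas, hits, operon_pairs,
                            pathways, truth)


def score_against_truth(
    predictions: Mapping[str, Iterable[str]],
    truth: FixtureTruth,
    seeds: Optional[Mapping[str, Iterable[str]]] = None,
) -> ConfusionCounts:
    """Score predicted gene lists against planted memberships.

    For each pathway, predicted genes are positives; planted members not
    used as seeds are the recall universe. TN counts the remaining target
    genes. Unknown genes or pathways raise a validation error.
    """
    total = ConfusionCounts()
    for pid, predicted in sorted(predictions.items()):
        if pid not in truth.pathways:
            raise ValidationError(f"unknown pathway {pid!r}")
        predicted = set(predicted)
        unknown = predicted - truth.target_gene_ids
        if unknown:
            raise ValidationError(f"unknown gene(s) {sorted(unknown)}")
        seed_set = set(seeds.get(pid, ())) if seeds else set()
        wanted = truth.pathways[pid] - seed_set
        tp = len(predicted & wanted)
        fp = len(predicted - truth.pathways[pid])
        fn = len(wanted - predicted)
        tn = len(truth.target_gene_ids) - len(seed_set) - tp - fp - fn
        total = total + ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    return total
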