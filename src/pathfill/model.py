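"""Domain types shared across the package.

The central objects are positional gene records grouped per genome, BLAST
homology hits, operon-pair probabilities, pathway memberships, and the
parameter bundle that controls graph construction, distance fusion and
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; carries the offending line."""


@dataclass(frozen=True, order=True)
class Gene:
    """A positional gene record: 1-based inclusive coordinates on a contig."""

    genome_id: str
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: strand must be one of {STRANDS}, "
                f"got {self.strand!r}"
            )


@dataclass(frozen=True)
class GenomeMeta:
    genome_id: str
    genus: str
    total_length: int
    is_target: bool = False

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValidationError(
                f"genome {self.genome_id}: total_length must be positive"
            )


@dataclass(frozen=True)
class HomologyHit:
    """One row of an all-vs-all similarity search; evalue is the BLAST E-value."""

    query_gene: str
    subject_gene: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(
                f"hit {self.query_gene}->{self.subject_gene}: negative E-value"
            )


@dataclass(frozen=True)
class OperonPair:
    """Probability that two neighbouring genes of one genome share an operon."""

    genome_id: str
    gene_a: str
    gene_b: str
    prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValidationError(
                f"operon pair {self.gene_a}/{self.gene_b}: probability "
                f"{self.prob} outside [0, 1]"
            )


@dataclass(frozen=True)
class Pathway:
    """A pathway with its known (seed) gene set G(P) in the target genome."""

    pathway_id: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"pathway {self.pathway_id}: empty gene set")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class Params:
    """Tunable parameters of graph construction, distance fusion and ranking.

    Defaults are the cross-validated operating point: per-seed path top list
    K=5, phylo top list K_phylo=50, similarity scaling alpha=380 (about twice
    the 185 E-value normalization, so one homology edge weighs about half an
    operon edge), fusion scaling beta=5, output size gamma=10, per-edge
    penalty system_error=0.06, and an E-value cutoff of 1e-3 both for
    similarity edges and for profile presence calls.

    alpha and beta may be zero so that a ±100% robustness sweep is
    well-defined at its lower endpoint: alpha=0 is the limit in which
    similarity edges become infinitely heavy (they are dropped from path
    search) and beta=0 removes the phylogenetic term from the fusion.
    """

    K: int = 5
    K_phylo: int = 50
    alpha: float = 380.0
    beta: float = 5.0
    gamma: int = 10
    system_error: float = 0.06
    profile_evalue_cutoff: float = 1e-3
    edge_evalue_cutoff: float = 1e-3
    norm: float = 185.0
    alpha_scope: str = "similarity"  # or "all": scale both edge-type sums
    aggregator: str = "mean"  # or "min": per-seed aggregation in the fusion
    common_mode: str = "union"  # or "all" / "agreement": profile common part
    entropy_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.K <= 0 or self.K_phylo <= 0:
            raise ValidationError("K and K_phylo must be positive")
        if self.gamma < 0:
            raise ValidationError("gamma must be non-negative")
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("alpha and beta must be non-negative")
        if self.system_error < 0:
            raise ValidationError("system_error must be non-negative")
        if self.profile_evalue_cutoff <= 0 or self.edge_evalue_cutoff <= 0:
            raise ValidationError("E-value cutoffs must be positive")
        if self.norm <= 0:
            raise ValidationError("norm must be positive")
        if self.alpha_scope not in ("similarity", "all"):
            raise ValidationError(f"unknown alpha_scope {self.alpha_scope!r}")
        if self.aggregator not in ("mean", "min"):
            raise ValidationError(f"unknown aggregator {self.aggregator!r}")
        if self.common_mode not in ("union", "all", "agreement"):
            raise ValidationError(f"unknown common_mode {self.common_mode!r}")
        if self.entropy_floor <= 0:
            raise ValidationError("entropy_floor must be positive")

    @property
    def absent_seed_cap(self) -> float:
        """Imputed per-seed distance for seeds whose top list omits a candidate.

        Roughly one maximal-weight penalized edge: 1.0 + system_error.
        """
        return 1.0 + self.system_error

    def with_(self, **kwargs) -> "Params":
        return replace(self, **kwargs)

    def key(self) -> tuple:
        """Hashable identity of the parameter bundle, for caching."""
        return tuple(getattr(self, f.name) for f in fields(self))


@dataclass(frozen=True)
class RankedCandidate:
    """A candidate gene with its fused distance to a pathway's seed set."""

    pathway_id: str
    gene: str
    path_distance: Optional[float]
    phylo_distance: Optional[float]
    combined: float
    T: int
    rank: int

    def __post_init__(self) -> None:
        n_defined = (self.path_distance is not None) + (
            self.phylo_distance is not None
        )
        if n_defined == 0:
            raise ValidationError(
                f"candidate {self.gene}: neither distance defined"
            )
        if self.T != n_defined:
            raise ValidationError(
                f"candidate {self.gene}: T={self.T} but {n_defined} "
                "distances defined"
            )
        if self.rank < 1:
            raise ValidationError(f"candidate {self.gene}: rank must be >= 1")


class GeneCatalog:
    """All genes of the dataset, ordered along each contig within each genome.

    Ordering is (contig, start, gene_id); adjacency for operon pairs is
    defined on consecutive genes of the same contig.
    """

    def __init__(self, genes: Iterable[Gene]):
        self._genes: dict[str, Gene] = {}
        by_genome: dict[str, list[Gene]] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g
            by_genome.setdefault(g.genome_id, []).append(g)
        self._by_genome = {
            gid: sorted(gs, key=lambda g: (g.contig, g.start, g.gene_id))
            for gid, gs in by_genome.items()
        }
        self._adjacent: set[frozenset] = set()
        for gs in self._by_genome.values():
            for a, b in zip(gs, gs[1:]):
                if a.contig == b.contig:
                    self._adjacent.add(frozenset((a.gene_id, b.gene_id)))

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __iter__(self) -> Iterator[Gene]:
        for gid in self.genomes:
            yield from self._by_genome[gid]

    def __getitem__(self, gene_id: str) -> Gene:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise ValidationError(f"unknown gene {gene_id!r}") from None

    @property
    def genomes(self) -> list:
        return sorted(self._by_genome)

    def genes_of(self, genome_id: str) -> Sequence[Gene]:
        try:
            return tuple(self._by_genome[genome_id])
        except KeyError:
            raise ValidationError(f"unknown genome {genome_id!r}") from None

    def gene_ids_of(self, genome_id: str) -> list:
        return [g.gene_id for g in self.genes_of(genome_id)]

    def genome_of(self, gene_id: str) -> str:
        return self[gene_id].genome_id

    def are_adjacent(self, gene_a: str, gene_b: str) -> bool:
        return frozenset((gene_a, gene_b)) in self._adjacent
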