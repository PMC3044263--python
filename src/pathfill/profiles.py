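"""Phylogenetic profiles and the entropy-weighted profile distance.

A gene's profile is a binary presence/absence vector across the n reference
genomes: position i is 1 when the gene has a homolog (E-value at or below
the cutoff) in the i-th genome. Genes that co-evolve — appearing and
disappearing together across lineages — have similar profiles, which is
evidence of shared function even without direct sequence similarity.

The distance between two profiles is the normalized Hamming distance
weighted by the informativeness of their shared signal:

    d_p(X, Y) = (hamming(X, Y) / n) / max(Entropy(X, Y), entropy_floor)

where Entropy(X, Y) is the binary entropy of p, the frequency of joint
presence among positions where at least one gene is present. A near-
constant common part (entropy near 0) means the agreement is uninformative
(e.g. both genes simply present everywhere), so the distance is inflated.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import GeneCatalog, HomologyHit, Params, ValidationError


def binary_entropy(p: float) -> float:
    """H(p) = -p*log2(p) - (1-p)*log2(1-p) in bits, with 0*log(0) = 0."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"probability {p} outside [0, 1]")
    if p in (0.0, 1.0):
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def hamming(x: Sequence[int], y: Sequence[int]) -> int:
    """Number of positions where two equal-length binary profiles differ."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValidationError(
            f"profile length mismatch: {x.shape} vs {y.shape}"
        )
    return int(np.count_nonzero(x != y))


def _common_part_frequency(x: np.ndarray, y: np.ndarray, mode: str) -> Optional[float]:
    """Frequency p of joint presence, under the configured reading.

    'union' (default): p = |both 1| / |either 1|; None when both profiles
    are empty. 'all': p = |both 1| / n. 'agreement': p = |both 1| /
    |positions where the profiles agree|; None when they disagree everywhere.
    """
    both = int(np.count_nonzero(x & y))
    if mode == "union":
        denom = int(np.count_nonzero(x | y))
    elif mode == "all":
        denom = x.size
    elif mode == "agreement":
        denom = int(np.count_nonzero(x == y))
    else:
        raise ValidationError(f"unknown common_mode {mode!r}")
    if denom == 0:
        return None
    return both / denom


def phylo_distance(
    x: Sequence[int],
    y: Sequence[int],
    eps: float = 0.05,
    common_mode: str = "union",
) -> Optional[float]:
    """Entropy-weighted profile distance; None when undefined.

    Undefined when either profile is all-zero (a gene absent from every
    reference genome carries no co-evolution signal). Symmetric, zero for
    identical non-empty profiles.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValidationError(
            f"profile length mismatch: {x.shape} vs {y.shape}"
        )
    if x.size == 0:
        raise ValidationError("profiles must have positive length")
    if not x.any() or not y.any():
        return None
    p = _common_part_frequency(x, y, common_mode)
    if p is None:
        return None
    h = max(binary_entropy(p), eps)
    return (hamming(x, y) / x.size) / h


class ProfileSet:
    """Profiles of target-genome genes over a fixed reference-genome order."""

    def __init__(self, genomes: Sequence[str], bits: Mapping[str, np.ndarray]):
        self.genomes = tuple(genomes)
        n = len(self.genomes)
        self._bits = {}
        for gene, vec in bits.items():
            vec = np.asarray(vec, dtype=bool)
            if vec.size != n:
                raise ValidationError(
                    f"profile of {gene}: length {vec.size} != {n} genomes"
                )
            self._bits[gene] = vec

    def __contains__(self, gene: str) -> bool:
        return gene in self._bits

    def __len__(self) -> int:
        return len(self._bits)

    @property
    def genes(self) -> list:
        return sorted(self._bits)

    def profile(self, gene: str) -> np.ndarray:
        try:
            return self._bits[gene]
        except KeyError:
            raise ValidationError(f"no profile for gene {gene!r}") from None

    def distance(self, gene_a: str, gene_b: str, params: Params) -> Optional[float]:
        return phylo_distance(
            self.profile(gene_a),
            self.profile(gene_b),
            eps=params.entropy_floor,
            common_mode=params.common_mode,
        )

    def topk(self, seed: str, params: Params) -> tuple:
        """K_phylo nearest genes to a seed, (gene, distance), ties by gene id.

        Pairs with undefined distance (either profile empty) are excluded.
        """
        entries = []
        for gene in self._bits:
            if gene == seed:
                continue
            d = self.distance(seed, gene, params)
            if d is not None:
                entries.append((d, gene))
        entries.sort()
        return tuple((gene, d) for d, gene in entries[: params.K_phylo])

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("gene_id\t" + "\t".join(self.genomes) + "\n")
            for gene in self.genes:
                row = "\t".join(str(int(b)) for b in self._bits[gene])
                fh.write(f"{gene}\t{row}\n")

    @classmethod
    def from_tsv(cls, path) -> "ProfileSet":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            genomes = header[1:]
            bits = {}
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                bits[fields[0]] = np.array([int(v) for v in fields[1:]], dtype=bool)
        return cls(genomes, bits)


def build_profiles(
    homology_hits: Iterable[HomologyHit],
    catalog: GeneCatalog,
    target_genome: str,
    reference_genomes: Sequence[str],
    cutoff: float = 1e-3,
) -> ProfileSet:
    """Profiles of all target-genome genes against the reference panel.

    Bit i is set when any hit (in either direction) between the gene and a
    gene of reference genome i has E-value <= cutoff. Hits touching unknown
    genes raise a validation error.
    """
    genomes = tuple(reference_genomes)
    index = {g: i for i, g in enumerate(genomes)}
    bits = {
        gid: np.zeros(len(genomes), dtype=bool)
        for gid in catalog.gene_ids_of(target_genome)
    }
    for hit in homology_hits:
        if hit.evalue > cutoff:
            continue
        for gene, other in (
            (hit.query_gene, hit.subject_gene),
            (hit.subject_gene, hit.query_gene),
        ):
            if gene in bits:
                genome = catalog.genome_of(other)
                i = index.get(genome)
                if i is not None:
                    bits[gene][i] = True
    return ProfileSet(genomes, bits)
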