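"""Readers and writers for the tabular input/output formats.

All files are plain TSV, UTF-8, with '#'-prefixed comment lines ignored.
The similarity input is BLAST tabular (outfmt-6 field order, E-value in
column 11). Readers validate domain invariants on the way in; writers
round-trip losslessly through the matching reader.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .model import (
    Gene,
    GeneCatalog,
    GenomeMeta,
    HomologyHit,
    OperonPair,
    ParseError,
    Pathway,
    RankedCandidate,
    ValidationError,
)

GENE_TABLE_COLUMNS = ("genome_id", "gene_id", "contig", "start", "end", "strand")
RANKING_COLUMNS = (
    "pathway_id",
    "rank",
    "gene_id",
    "path_distance",
    "phylo_distance",
    "combined_distance",
)


def _rows(path) -> Iterable[tuple[int, list]]:
    """Yield (1-based line number, fields) for data lines of a TSV file."""
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _skip_header(rows, first_column: str):
    rows = iter(rows)
    try:
        lineno, fields = next(rows)
    except StopIteration:
        return
    if fields[0] != first_column:  # header optional
        yield lineno, fields
    yield from rows


def read_gene_table(path) -> GeneCatalog:
    """Read a TSV gene table into a catalog ordered by (contig, start)."""
    genes = []
    for lineno, fields in _skip_header(_rows(path), "genome_id"):
        if len(fields) != 6:
            raise ParseError(
                f"{path}:{lineno}: expected 6 tab-separated fields, "
                f"got {len(fields)}"
            )
        genome_id, gene_id, contig, start, end, strand = fields
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-integer coordinates {start!r}/{end!r}"
            ) from None
        genes.append(Gene(genome_id, gene_id, contig, start_i, end_i, strand))
    return GeneCatalog(genes)


def write_gene_table(catalog: GeneCatalog, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENE_TABLE_COLUMNS)
        for g in catalog:
            w.writerow([g.genome_id, g.gene_id, g.contig, g.start, g.end, g.strand])


def read_blast_tabular(path) -> list:
    """Read BLAST outfmt-6 rows into homology hits; self-hits are dropped.

    Only qseqid (col 1), sseqid (col 2) and evalue (col 11) are used; the
    reader preserves both directions of asymmetric hit pairs, which are
    symmetrized downstream by taking the minimum E-value.
    """
    hits = []
    for lineno, fields in _rows(path):
        if len(fields) < 11:
            raise ParseError(
                f"{path}:{lineno}: expected >= 11 BLAST tabular columns, "
                f"got {len(fields)}"
            )
        query, subject = fields[0], fields[1]
        try:
            evalue = float(fields[10])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric E-value {fields[10]!r}"
            ) from None
        if not math.isfinite(evalue):
            raise ParseError(f"{path}:{lineno}: non-finite E-value {fields[10]!r}")
        if query == subject:
            continue
        hits.append(HomologyHit(query, subject, evalue))
    return hits


def write_blast_tabular(hits: Iterable[HomologyHit], path) -> None:
    """Write hits in 12-column outfmt-6 layout; unused columns are zeroed."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            w.writerow(
                [h.query_gene, h.subject_gene, 0, 0, 0, 0, 0, 0, 0, 0,
                 repr(h.evalue), 0]
            )


def read_operon_pairs(path, catalog: Optional[GeneCatalog] = None) -> list:
    """Read operon-pair probabilities; with a catalog, adjacency is enforced."""
    pairs = []
    for lineno, fields in _skip_header(_rows(path), "genome_id"):
        if len(fields) != 4:
            raise ParseError(
                f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
            )
        genome_id, gene_a, gene_b, prob = fields
        try:
            prob_f = float(prob)
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric probability {prob!r}"
            ) from None
        pair = OperonPair(genome_id, gene_a, gene_b, prob_f)
        if catalog is not None:
            for gid in (gene_a, gene_b):
                if catalog.genome_of(gid) != genome_id:
                    raise ValidationError(
                        f"{path}:{lineno}: gene {gid} is not in genome "
                        f"{genome_id}"
                    )
            if not catalog.are_adjacent(gene_a, gene_b):
                raise ValidationError(
                    f"{path}:{lineno}: genes {gene_a}/{gene_b} are not "
                    "neighbours on a contig"
                )
        pairs.append(pair)
    return pairs


def write_operon_pairs(pairs: Iterable[OperonPair], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "gene_a", "gene_b", "prob"])
        for p in pairs:
            w.writerow([p.genome_id, p.gene_a, p.gene_b, repr(p.prob)])


def read_pathways(path, catalog: Optional[GeneCatalog] = None,
                  target_genome: Optional[str] = None) -> list:
    """Read pathway membership (pathway_id, gene_id) rows into pathways."""
    members: dict[str, set] = {}
    order: list[str] = []
    for lineno, fields in _skip_header(_rows(path), "pathway_id"):
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
            )
        pathway_id, gene_id = fields
        if catalog is not None and gene_id not in catalog:
            raise ValidationError(f"{path}:{lineno}: unknown gene {gene_id!r}")
        if (
            catalog is not None
            and target_genome is not None
            and catalog.genome_of(gene_id) != target_genome
        ):
            raise ValidationError(
                f"{path}:{lineno}: pathway gene {gene_id} is not in the "
                f"target genome {target_genome}"
            )
        if pathway_id not in members:
            order.append(pathway_id)
        members.setdefault(pathway_id, set()).add(gene_id)
    return [Pathway(pid, frozenset(members[pid])) for pid in order]


def write_pathways(pathways: Iterable[Pathway], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["pathway_id", "gene_id"])
        for p in pathways:
            for gid in sorted(p.genes):
                w.writerow([p.pathway_id, gid])


def read_genome_metadata(path) -> list:
    metas = []
    for lineno, fields in _skip_header(_rows(path), "genome_id"):
        if len(fields) != 4:
            raise ParseError(
                f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
            )
        genome_id, genus, total_length, is_target = fields
        try:
            length = int(total_length)
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-integer total_length {total_length!r}"
            ) from None
        metas.append(GenomeMeta(genome_id, genus, length, is_target == "1"))
    n_targets = sum(m.is_target for m in metas)
    if metas and n_targets != 1:
        raise ValidationError(
            f"{path}: exactly one genome must be flagged as target, "
            f"found {n_targets}"
        )
    return metas


def write_genome_metadata(metas: Iterable[GenomeMeta], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "genus", "total_length", "is_target"])
        for m in metas:
            w.writerow([m.genome_id, m.genus, m.total_length, int(m.is_target)])


def select_reference_genomes(metas: Sequence[GenomeMeta]) -> list:
    """One reference genome per genus: the one with the longest sequence.

    Ties are broken by the lexicographically smallest genome id so the
    selection is deterministic. The target genome is not eligible.
    """
    best: dict[str, GenomeMeta] = {}
    for m in metas:
        if m.is_target:
            continue
        cur = best.get(m.genus)
        if (
            cur is None
            or m.total_length > cur.total_length
            or (m.total_length == cur.total_length and m.genome_id < cur.genome_id)
        ):
            best[m.genus] = m
    return sorted(m.genome_id for m in best.values())


def write_rankings(candidates: Sequence[RankedCandidate], path) -> None:
    """Write ranked candidates as TSV; undefined distances are empty fields."""
    for c in candidates:
        for v in (c.path_distance, c.phylo_distance, c.combined):
            if v is not None and not math.isfinite(v):
                raise ValidationError(
                    f"candidate {c.gene}: non-finite distance {v}"
                )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RANKING_COLUMNS)
        for c in candidates:
            w.writerow([
                c.pathway_id,
                c.rank,
                c.gene,
                "" if c.path_distance is None else repr(c.path_distance),
                "" if c.phylo_distance is None else repr(c.phylo_distance),
                repr(c.combined),
            ])


def read_rankings(path) -> list:
    out = []
    for lineno, fields in _skip_header(_rows(path), "pathway_id"):
        if len(fields) != 6:
            raise ParseError(
                f"{path}:{lineno}: expected 6 fields, got {len(fields)}"
            )
        pathway_id, rank, gene, d_path, d_phylo, combined = fields
        path_d = None if d_path == "" else float(d_path)
        phylo_d = None if d_phylo == "" else float(d_phylo)
        T = (path_d is not None) + (phylo_d is not None)
        out.append(
            RankedCandidate(
                pathway_id, gene, path_d, phylo_d, float(combined), T, int(rank)
            )
        )
    return out
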