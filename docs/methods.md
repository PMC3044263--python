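# Methods

`pathfill` ranks genes of a target prokaryotic genome as candidates for
membership in a partially known pathway ("pathway holes"). It fuses two
complementary genomic-context signals: proximity in a cross-genome
operon/homology graph, and similarity of phylogenetic (co-occurrence)
profiles. This note records the model, every parameter, the numerical
choices, what the synthetic benchmark emulates, and the limitations.

## 1. Model

### 1.1 Inputs

- A **gene table**: one row per gene with genome, contig, strand and
  coordinates, for the target genome and a panel of reference genomes.
- **All-vs-all homology hits** (BLAST tabular, outfmt 6); only the E-value
  column is used. Self-hits are discarded; asymmetric hit pairs are
  symmetrized by taking the minimum E-value of the two directions.
- **Operon-pair probabilities**: for each pair of adjacent same-strand genes
  on a contig, the probability `p_o ∈ [0, 1]` that the pair is co-operonic.
- **Pathway memberships**: known member genes `G(P)` of each pathway in the
  target genome (the seeds).
- **Genome metadata** marking exactly one genome as the target. When a panel
  is not given explicitly, reference genomes are selected one per genus
  (largest genome; ties broken by smallest genome id), excluding the target.

### 1.2 Edge distances

Homology hits with E-value ≤ `edge_evalue_cutoff` become **similarity
edges** between genes of *different* genomes, with distance

    d_s(E) = clamp(1 + log10(E) / norm, 0, 1),      d_s(0) = 0

so `E = 10^-norm` (the reported floor of E-value exponents) maps to 0 and
`E = 0.1` maps to ≈ 1. Adjacent same-genome gene pairs with an operon
probability become **operon edges** with distance

    d_o(p_o) = 1 − p_o.

All genes of all genomes are vertices of one **reference graph**; similarity
edges are never created within a genome (intra-genome paralog hits are read
but do not become edges).

### 1.3 Penalized path distance

The distance of a path with operon-edge set `O`, similarity-edge set `S` and
`k = |O| + |S|` edges is

    D = Σ_{e∈O} d_o(e) + (norm / α) · Σ_{e∈S} d_s(e) + k · system_error.

The per-edge penalty `system_error` charges every hop for the chance that
the underlying call (a homology hit, an operon prediction) is wrong, so long
chains of individually plausible links are discounted. Because the penalty
and the `norm/α` scaling are per-edge-type constants, `D` decomposes into a
sum of nonnegative effective edge weights

    w(e) = d_o(e) + system_error                     (operon edge)
    w(e) = (norm / α) · d_s(e) + system_error        (similarity edge)

and the minimum over paths is computed **exactly** by Dijkstra's algorithm
on those weights — no heuristic search is involved. `alpha_scope="all"`
applies the `norm/α` factor to both sums instead.

For each seed gene `s ∈ G(P)` the `K` nearest target-genome genes by this
distance form the seed's **linkage list**; the union of linkage lists is the
candidate pool on the path side.

### 1.4 Phylogenetic profiles

The profile of a target gene is the binary presence vector over the `n`
reference genomes: genome `j` is 1 if any hit in either direction between
the gene and a gene of genome `j` has E-value ≤ `profile_evalue_cutoff`.
For two profiles `x, y`:

    p = |{j : x_j = 1 and y_j = 1}| / |{j : x_j = 1 or y_j = 1}|
    d_p(x, y) = (Hamming(x, y) / n) / max(H(p), entropy_floor)

where `H` is the binary entropy (bits). The entropy weight rewards
*informative* agreement: two genes co-present in about half the panel are
stronger evidence of functional coupling than two genes present everywhere.
`common_mode` selects the denominator of `p` (`union` default, `all` = n,
`agreement` = positions where the profiles agree). A gene absent from every
reference genome has an undefined profile distance and is excluded from the
phylo term. Per seed, the `K_phylo` nearest defined target genes form the
phylo candidate list.

### 1.5 Fusion and ranking

For a candidate gene `g` and pathway `P`, each signal is aggregated over the
seeds. With the default mean aggregator, a seed whose top-`K` linkage list
omits `g` contributes the cap `1 + system_error` (just beyond the worst
usable single-edge distance); with `aggregator="min"` the best seed is
taken and missing seeds are skipped. The phylo term `d_phylo(g, P)` is the
same aggregation of `d_p`. The fused score is

    combined(g, P) = (d_path(g, P) + β · d_phylo(g, P)) / T

where `T ∈ {1, 2}` counts the defined terms (the phylo term can be
undefined). Candidates — the union of all seeds' path and phylo top lists,
minus the seeds themselves — are sorted by `(combined, −T, gene_id)` and the
top `γ` are reported. The `−T` tie-break prefers candidates supported by
both signals; the gene-id tie-break makes output deterministic.

### 1.6 Evaluation

**Leave-one-out (LOO):** each member of `G(P)` is held out in turn and the
remaining members seed a ranking. The held-out gene is a TP if it appears
in the top `γ`, else an FN, so `TP + FN = |G(P)|`. FP is the number of
*distinct* non-member target genes appearing in any of the `|G(P)|` top
lists (pooled, not per-trial), and TN is the rest of the target genome.
Then SE = TP/(TP+FN), SP = TN/(TN+FP), PPV = TP/(TP+FP); any metric with a
zero denominator is `None` and excluded (never coerced to 0). Multi-pathway
averages are unweighted means over pathways; singleton pathways are skipped
with a warning.

**Ten-fold cross-validation:** pathways are shuffled with a seeded
permutation into ten folds (fewer, with a warning, if there are fewer than
ten pathways). Each grid point is scored by the mean over folds of the mean
test-fold PPV; ties go to the lexicographically smaller parameter tuple.

**Robustness sweep:** a parameter `x ∈ {alpha, beta, system_error}` is
re-evaluated at `x₀ · (1 + r)` for change rates `r ∈ [−1, 1]`, reporting
the relative PPV change. Rate 0 reuses the baseline result object, so its
change rate is exactly 0 by construction.

**Recall graph (module structure):** for a pathway, each member `a` alone
seeds a ranking; a directed recall `a → b` for members `b` in the top `γ`
contributes an undirected edge. Connected components of this graph expose
sub-modules that recall each other but not the rest of the pathway.

## 2. Parameters

| Name | Default | Units / range | Rationale |
|---|---|---|---|
| `K` | 5 | genes | per-seed linkage list size; small keeps the pool local |
| `K_phylo` | 50 | genes | per-seed phylo list size; profiles are cheap, cast wider |
| `alpha` | 380 | dimensionless | similarity scaling; ≈ 2·norm, so a similarity edge weighs about half an operon edge |
| `beta` | 5 | dimensionless | phylo weight in fusion; `d_p` values are small relative to path distances |
| `gamma` | 10 | genes | output list size; also the LOO recall window |
| `system_error` | 0.06 | distance per edge | per-hop penalty for call errors; 0 recovers the classic shortest path |
| `edge_evalue_cutoff` | 1e-3 | E-value | similarity-edge admission |
| `profile_evalue_cutoff` | 1e-3 | E-value | profile presence call |
| `norm` | 185 | log10 E-value | E-value exponent floor used by `d_s` |
| `entropy_floor` | 0.05 | bits | keeps `d_p` finite when `H(p) → 0` |
| `alpha_scope` | `similarity` | — | which edge sums `norm/α` scales |
| `aggregator` | `mean` | — | per-seed aggregation (cap imputation `1 + system_error`) vs `min` |
| `common_mode` | `union` | — | denominator of the common-part frequency `p` |

`alpha` and `beta` are allowed to be 0, deviating from a strict positivity
invariant, so the sweep's −100% endpoint is well-defined: `alpha = 0` is
the limit where similarity edges become infinitely heavy and are excluded
from path search; `beta = 0` removes the phylo term.

## 3. Synthetic benchmark: what it emulates, and what it does not

The generator (`pathfill.simulate`) plants pathways as scattered genes in a
200-gene target genome, with orthologs arranged as adjacent high-probability
operon runs in a conserved subset of reference genomes — the
similarity → operon → similarity chains the method exploits. Ortholog hits
get strong E-values (exponents 30–185), background hits weak ones (5–30),
plus sparse noise edges and occasional intra-target paralog hits.
`operon_conservation` is the fraction of reference genomes in which a
planted pathway is conserved, and governs **both** ortholog presence and
operonic arrangement: at 0, planted genes have no homologs at all — the
negative control in which recovery collapses. `disjoint_conservation`
assigns each pathway its own disjoint conserved-genome subset, separating
the profiles of different pathways. All randomness flows from one
`numpy.random.default_rng(seed)`; datasets are byte-reproducible.

It does **not** emulate: actual sequences or alignment (E-values are drawn,
not computed); genome rearrangement, gene fusion/fission, or horizontal
transfer; realistic operon-prediction error structure; panel sizes beyond a
dozen genomes. Two consequences to keep in mind when reading numbers:

- **Profile collisions at full conservation.** On a small panel at
  conservation 1.0, every planted gene of every pathway has the all-ones
  profile, so phylo distances between cross-pathway genes are 0 and the
  profile term is uninformative. The multi-pathway report fixture therefore
  uses partial, lineage-specific conservation (12 genomes, conservation
  2/3) — the regime the profile signal assumes. Even so, at this desk
  scale the phylo term's marginal PPV contribution (`ppv_gain_phylo` in the
  acceptance report) is measured **negative**: profiles admit look-alike
  genes from other conserved pathways faster than they promote true
  members. This is reported honestly, not suppressed.
- **PPV scale.** With `γ = 10` predictions per trial pooled against
  pathways of 4–6 members, PPV is bounded well below 1 even at perfect
  sensitivity; PPV ≈ 0.33–0.4 on the report fixtures reflects the
  `γ`/pathway-size ratio, not ranking failure (SE is 1.0 on the same
  fixtures).

## 4. Numerical and degenerate-case choices

- **Deterministic Dijkstra:** heap entries are `(distance, edge count,
  vertex-path tuple)`, so equal-distance ties resolve to the fewest-edge,
  lexicographically smallest path, and witness paths are reproducible.
- **Exactness:** the penalty folds into per-edge weights, so the oracle
  check against exhaustive simple-path enumeration agrees to < 1e-9.
- `d_s(0) = 0` by definition (log of 0 is otherwise undefined);
  `d_s` clamps to `[0, 1]`.
- Undefined quantities are `None`, never 0: SE/SP/PPV with zero
  denominators, profile distance of an all-zero profile, seeds with no
  reachable candidates.
- Unreachable vertices simply do not appear in linkage lists; a ranking may
  legitimately return fewer than `γ` candidates, or none.
- Input validation is strict: unknown gene ids, non-adjacent operon pairs,
  multiple target genomes, NaN scores and singleton pathways (for LOO) all
  raise typed errors rather than propagating silently.

## 5. Interpretation choices (under-determined details)

Several details of the method admit multiple readings; the resolution is
recorded here and, where reasonable, kept configurable:

- **Placement of α:** scales the similarity-edge sum only (default); the
  `alpha_scope="all"` alternative scales both sums.
- **"Common part" of two profiles:** intersection-over-union frequency
  (default), with `all` and `agreement` alternatives.
- **Seed aggregation:** mean over all seeds with cap imputation (default),
  because it rewards candidates near *many* seeds; `min` is the optimistic
  alternative.
- **Recall-graph seeding:** each member seeds alone (singleton seeding),
  which isolates pairwise recall structure; seeding with all-but-one would
  blur module boundaries.
- **Pooled FP universe in LOO:** distinct false positives across the
  `|G(P)|` trials, counted against the whole target genome, so SP and PPV
  describe the pathway-level prediction set rather than one trial.
- **Adjacency is per contig:** operon pairs may only join coordinate-
  adjacent, same-contig genes; no circular wrap-around is assumed.

## 6. Limitations

- E-values stand in for homology; no sequence-level confounders (domain
  sharing, low-complexity matches) are modeled.
- The benchmark panel is small; profile entropy weighting is coarse at
  n ≤ 12, and `ppv_gain_phylo` should be re-measured before trusting the
  phylo term on real panels.
- PPV depends on `γ` and pathway size (see §3); compare PPVs only at fixed
  `γ`.
- Ten-fold CV over few pathways degenerates to fewer folds; selections on
  small fixtures mostly exercise the machinery, not the statistics.
- Runtime is dominated by one Dijkstra per seed per parameter point;
  per-seed caching makes LOO/CV/sweeps cheap at benchmark scale, but a
  full-scale panel (dozens of genomes, thousands of genes each) would want
  a multi-source or bounded-radius search.
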