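# Methods

This note records the models, numerical choices and limitations behind
`structcore`, in the order the pipeline runs.

## Scoring model

Both alphabets (amino acids and 3Di structural states) use the same 20
uppercase letters; `X` is the wildcard and scores 0 against everything,
including itself. An aligned column scores

    S(i, j) = round( w3di · S3di(t_i, t_j) + waa · Saa(a_i, a_j) )

with channel weights `w3di = 2.1`, `waa = 1.4` (the weighting convention
popularised by structure-aware alignment tools) and affine gaps
(open 10, extend 1, applied to the combined scale). Rounding the weighted
sum once per pair keeps raw scores integral. The amino-acid matrix is
BLOSUM62 (from biopython, with the X row/column overridden to 0). The
structural matrix shipped in `data/mat3di.synthetic.txt` is a synthetic
uniform matrix (match +6, mismatch −3): it is *not* the matrix any
particular structure-search tool distributes, but a neutral default matched
to the uniform substitution process of the synthetic generator; any
NCBI-format matrix can be substituted via `read_ncbi_matrix` /
`--mat3di`. Both matrices must be symmetric with negative expected score
under the uniform background, which the model validates.

**E-values.** Significance follows the Karlin–Altschul form
`E = m · n_db · 2^(−bit)` with `bit = (λ·raw − ln K)/ln 2`, where `m` is the
query length and `n_db` the total residue count of the search space at the
round where the alignment is evaluated. Because no published (λ, K) exists
for an arbitrary combined matrix, the model estimates them once per scoring
scheme: 300 random sequence pairs of length 150 are drawn from the uniform
background, their optimal gapped local alignment scores are fitted with a
Gumbel distribution (scipy), and λ = 1/scale, K = exp(λ·loc)/(150·150). The
fit uses a fixed internal seed and is cached per scheme, so E-values are
deterministic across runs and processes. This is a crude but honest
calibration: E-values are accurate enough to rank and threshold hits at
E ≤ 10⁻³, not to be compared across very different scoring schemes.

## Alignment kernels

Pairwise hits use Smith–Waterman local alignment with affine gaps on the
precomputed combined score matrix (numba-compiled; a traceback-free variant
propagates alignment start coordinates for fast coverage screening, and a
traceback variant supplies aligned columns and amino-acid identity).
Profile–profile steps in the multiple aligner use global
Needleman–Wunsch with affine gaps, terminal gaps penalised like internal
ones. Tie-breaking is fixed "high-road": on equal scores the diagonal move
is preferred, then the vertical move, then the horizontal one, making every
alignment deterministic.

## Clustering

The prefilter is Linclust-style minimizer hashing: each sequence selects
its 21 lowest-hashing 3Di 6-mers (keyed blake2b, so selection is
deterministic per seed and identical strings always select identical sets).
Sequences sharing a selected k-mer become alignment candidates, ordered by
shared-k-mer count and capped at `max_seqs` (default: the larger of 1,000
and 20× the species count). One greedy round processes sequences longest
first: each still-unassigned sequence becomes a centroid and absorbs the
candidates that pass E ≤ 10⁻³ and ≥ 80% coverage of both sequences. Two
cascaded rounds are run by default (the second over the representatives of
the first; merged clusters union their members) — desk-scale databases
saturate after two — followed, by default, by a reassignment pass aligning
every non-representative member against all representatives and moving it
to the best bit score (singletons if none pass). An exact pruning skips
pairs whose length ratio alone makes 80% coverage impossible.

The package also provides a brute-force all-vs-all greedy set-cover
clusterer. It is quadratic and intended as an oracle: on replicate
synthetic databases the quasilinear clustering must agree with it at
adjusted Rand index ≥ 0.95 (it measures agreement of the two algorithms,
not truth recovery; both are additionally scored against the planted
families).

## Core-gene selection

Single-copy coverage of a cluster = fraction of *all* input species with
exactly one member in it; `any_copy_coverage` counts species with at least
one member and is exposed so users can apply their own multi-copy cutoff
(none is hard-coded). Selection is inclusive (coverage ≥ t): a cluster at
exactly the threshold is kept. A proteome triggers a warning when it is
present single-copy in fewer than a strict majority (⌈(n+1)/2⌉) of the
selected core genes. Diagnostics for comparing against an external gene
set: a gene maps to the cluster holding ≥ 80% of its members; an unmapped
gene counts as *fragmented* when the representatives of its two largest
overlapping clusters align significantly (E < 10⁻³) but with coverage
below 0.8 on either side.

## Multiple alignment, projection, supermatrix

Per core gene, only the single-copy members are aligned. The guide tree is
neighbor joining on `d = 1 − raw(a,b)/min(raw(a,a), raw(b,b))`; profiles
are merged along it, columns scored by the mean pairwise combined score
over non-gap row pairs (computed exactly, without the integer rounding of
the pairwise kernel, via the factorised bilinear forms). Columns whose gap
fraction is ≥ 50% are then removed (`-` only; `X` is a residue); removing
every column of a gene is a hard error naming the gene. Filtering happens
*before* amino-acid projection; every alignment carries a per-row map from
aligned cells to original residue indices, so the projection of a filtered
alignment selects exactly the residues at kept positions and is validated
against the database record. Projected alignments are concatenated in gene
order; species missing a gene receive all-gap blocks; partitions are
written 1-based inclusive as `JTT+F+I+G, <gene> = <start>-<end>` — the
model string documents what an external ML tool should be run with, the
built-in builder does not use it.

## Trees

The built-in builder is distance-based, not maximum likelihood: Poisson-
corrected amino-acid distances `d = −ln(1 − p)` over pairwise gap-free,
unambiguous columns (p ≥ 0.95 clamps to d = 3.0 with a warning; a pair with
zero overlap is an error), then canonical Saitou–Nei neighbor joining with
taxa processed in sorted order, first-minimum tie-breaking and negative
branch lengths clamped to zero — deterministic and input-order invariant.
Maximum-likelihood inference is deliberately delegated: `run_external_tree`
shells out to an installed tool, forwarding user options verbatim, and
parses its newick; it is an interface hook only. Bootstrap support is
classical Felsenstein column resampling (default 100 replicates at desk
scale; configurable), reported as the percentage of replicate NJ trees
containing each internal split, stored as internal-node labels.

**MAD rooting.** For a candidate root at distance x from node u on a branch
(u, v), every leaf pair (b, c) deviates by `r = |2·d(a,b)/d(b,c) − 1|`,
where a is the pair's ancestor under that rooting (the root itself for
pairs spanning the branch); pairs with zero path length contribute 0. The
mean of r² is exactly quadratic in x for each branch, so the optimal
position is solved in closed form (clamped to the branch) and the branch
with the smallest RMS deviation wins, ties resolved by branch traversal
order. The root is inserted as a degree-2 node; unrooted topology and total
branch length are preserved. On a clocklike tree the score is 0 at the
clock root.

**Metrics.** Quartet similarity enumerates all C(n,4) subsets and compares
induced topologies via the four-point condition on path-length matrices —
O(n⁴), fine at desk scale, and simple enough to double as its own oracle.
Ultrametricity is reported as the coefficient of variation of root-to-leaf
path lengths (0 = clocklike, scale-invariant), and reference congruence as
the fraction of reference-resolved quartets reproduced (multifurcation-
induced unresolved quartets excluded from the denominator). Both are
surrogates in the spirit of published tree-quality metrics, not
re-implementations of any specific tool's formula.

## Synthetic data

The generator draws a random coalescent-style ultrametric species tree
scaled to a configurable height, one root AA and one root 3Di string per
family, and evolves both down the tree under independent uniform
(Jukes–Cantor-like) substitution: on a branch of length t each site is
resampled uniformly from all 20 letters with probability
`1 − exp(−(20/19)·rate·t)`, giving the closed-form identity expectation
used in tests. No indels are simulated, so a family's true alignment is the
identity column map. Per species, a core family is lost with `loss_prob`
(all copies) or duplicated with `dup_prob` (one extra copy, re-diverged by
an extra 10% of the tree height); draws are rejection-sampled so a planted
core family's realized single-copy coverage never falls below
`core_coverage_floor` (default 0.8) — otherwise the planted label itself
would be ambiguous at the selection threshold. Accessory families are
planted in a random 20–60% minority of species, capped below the floor.
Everything derives from one seed; identical configs give byte-identical
outputs.

Default conditions: 20 species, 50 core + 50 accessory families, lengths
120–400, tree height 0.5, `rate_aa = 0.5`, `rate_3di = 0.15`, loss 0.1,
duplication 0.05 — a detectable-homology regime sized so the full pipeline
runs in minutes on one CPU. The twilight preset (`rate_aa = 2.5`,
`rate_3di = 0.08`) pushes mean within-family AA identity below 30% while
3Di identity stays above 80%, the regime where structure-aware scoring must
rescue pairs that amino-acid-only scoring misses.

What the generator does **not** emulate: indels (so the aligner's gap
handling is exercised only by hand-crafted cases and length differences
from fragments), compositional bias, domain shuffling, rate variation
across sites, correlated AA/3Di substitution, or structurally realistic
3Di strings. Passing tests therefore demonstrate the pipeline's internal
correctness and its behaviour under decoupled sequence/structure
divergence — not performance on real proteomes.

## Problem sizes used in tests

The acceptance checks run the full pipeline on the default 20-species
conditions (~1,400 records), the clustering-oracle comparison on five
~200-record databases (10 species × 20 families, lengths 80–160), the
twilight comparison on three 10-species × 5-family datasets (lengths
150–250), and tree recovery on 12-species × 20-family datasets at default
and doubled substitution rates. These sizes keep the whole suite at a few
minutes on one CPU while leaving every stage non-trivial.

## Known limitations and open choices

- The built-in tree is NJ; bootstrap values and branch lengths are not
  comparable to ML output. Use the delegation hook for publication trees.
- E-value calibration is scheme-specific and approximate (see above).
- The `-g` flag of the original createdb convention has no documented
  meaning and is ignored; proteins whose 3Di string cannot be resolved are
  dropped with a warning.
- Per-gene trees are emitted both unrooted and MAD-rooted, since no
  convention is established for rooting them.
- Cluster representatives are chosen by length (ties by id); other centroid
  policies would be equally defensible.
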