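# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the synthetic benchmarks demonstrate.

## Inputs and the mutation matrix

The pipeline consumes four inputs: somatic mutation calls (MAF; gene,
sample barcode, variant classification, position), pathway definitions
with undirected topology (a plain-text gene/edge dialect), a per-gene
covered-base table (bases with sufficient read depth, produced upstream by
coverage tooling), and a per-mutation functional-impact table keyed on
(gene, sample, position).

Each mutation is scored by class: indel, nonsense and splice-site variants
receive the highest attainable impact score (they are assumed at least as
disruptive as the worst missense change), silent variants the lowest, and
missense variants their own score or, when unscored, the cohort-wide mean
missense score. Impact bounds are derived from the cohort's scored
missense mutations unless supplied explicitly. Variants of any other class
fall outside the scoring rule and are skipped (counted and logged).

The cohort is then a pair of n×m matrices: for gene *i*, sample *j*,
`M_ij = Σ (bases × impact) / covered_bases(i)`, accumulated separately for
non-synonymous (NSY) and synonymous (SY) events, with raw event counts
kept alongside. Every mutation defaults to one mutated base; an explicit
length column is honoured when the MAF provides one. Coverage is per gene,
not per gene-per-sample. The gene universe of the matrix is the union of
mutated genes and all pathway genes, so unmutated pathway members carry
all-zero rows and need no coverage entry.

## Gene scores

**Mutation Factor.** `MF_i = (N_NSY / max(N_SY, 1)) · mean_j(M_ij_NSY −
M_ij_SY)`. The `max(·,1)` guard keeps the count-ratio weight defined for
genes without synonymous events — common in practice — without
pseudocounting observed data. The mean runs over all m samples.

**Interaction Factor.** Within a pathway, a pair's influence combines
shortest-path hop count *d* (hence influence decays with functional
distance; disconnected pairs exert none), exclusive pairwise coverage *C*
(fraction of samples where exactly one of the two genes is NSY-mutated)
and mutual exclusivity *ME* (exclusive over union):

    f_ij = C_ij · ME_ij / (1 + d_ij)

`IF_i` averages f over all |P|−1 partners, a partner contributing only
when `f ≥ α` (default α = 0.005; failing partners stay in the
denominator). When no partner passes, IF is floored at α so the ranking
score `exp(MF)·IF` stays strictly positive; α is the smallest meaningful
interaction scale already present in the configuration. With d ≥ 1 off the
diagonal and C·ME ≤ 1, IF lies strictly inside (0, 1).

**Imputation for outside genes.** Each pathway's ranked list must contain
every gene, but topology-dependent IF values only exist for members.
Outside genes therefore draw from a background Normal parameterised by the
mean and standard deviation of all real (member) scores across all
pathways — with probability equal to the pathway's fraction of α-passing
members — and otherwise fall back to `exp(MF)·α`, exactly the score a
member with no passing partner would receive. Draws are truncated below at
1e−12 to keep scores positive. This preserves the passing/non-passing
mixture between members and non-members and avoids rank bias toward
in-pathway genes.

## The weighted KS test

Walking the ranked list from the top, the member CDF accumulates member
*scores* (GSEA-style weighting) while the non-member CDF takes uniform
steps; the statistic is the maximum absolute deviation (MD). Exactly tied
scores — frequent at the α floor — form one atomic block: both CDFs jump
together and the deviation is read at block ends only, so MD does not
depend on an arbitrary within-tie ordering. For distinct scores this
equals the plain per-position walk, which the test suite verifies against
an independent brute-force scan.

**Permutation null.** The default null shuffles each member gene's
mutation profile independently across samples (preserving its mutated
sample count), recomputes the pairwise statistics and member scores, and
re-evaluates MD against the pathway's fixed imputed outside list. Two
observations make this exact scheme cheap: MF is invariant under a profile
shuffle (it averages over all samples), so only IF needs recomputation,
vectorised across permutations; and because the hit CDF is constant
between member jumps, MD can be evaluated at the 2k member merge points
against the sorted outside scores instead of re-walking the whole list.

A cheaper alternative null that shuffles membership *labels* over the
fixed ranked list is available (`perm_scheme="membership"`), but it is not
calibrated: member scores share pairwise interaction terms and are
strongly correlated, which label shuffling ignores. On null cohorts it
produced a KS distance of 0.22 from uniformity with spurious FDR
discoveries, versus ≈0.04 for the profile scheme; it is kept only as a
quick screen.

**Ties and the reported p.** With few mutated samples per gene the
permuted MD is discrete — in sparse null cohorts more than half the
permutations can tie the observed value exactly — so a plain ≥-count
p-value is severely conservative. The reported p splits the tie mass
uniformly at random using the run's seeded generator:

    p = (#{MD_perm > MD_obs} + 1 + U·#{MD_perm = MD_obs}) / (n_perm + 1)

the classical randomized construction, exactly valid and calibrated under
exchangeability, with minimum 1/(n_perm+1) so downstream FDR screening
stays conservative. Multiple testing uses the rank-based form
`FDR = p·m/k` (m = total pathways, k = rank), swept with a cumulative
minimum from the bottom so reported FDRs are monotone in rank, and capped
at 1.

## Collaborative set search

A pathway covers a sample when ≥1 member gene carries an NSY mutation
there; a set's MCR is the fraction of samples covered by every member
(intersection coverage, non-increasing as the set grows). Starting from
the top 60 enriched pathways, each greedy step ranks the remaining
candidates by the joint MCR they would produce (ties broken by enrichment
rank) and takes the first one that passes:

* **dominance** — joint MCR ≥ top single-gene rate + δ (default δ = 0.05,
  boundary passes, ties among genes broken alphabetically). This rejects
  pathway coverage manufactured by one hypermutated gene.
* **collaboration significance** — every NSY event of the candidate's
  genes is reassigned to a uniformly random sample (with replacement,
  total count preserved); the background MCR is the permuted candidate's
  coverage intersected with the already-selected pathways' observed
  coverage, and the candidate needs `#{background ≥ observed}/n_perm`
  strictly below 0.01. A candidate without events gets p = 1.

The first pathway has no partners and is exempt from the permutation test
but not from dominance. The walk stops when no candidate qualifies; an
empty set is a legal outcome. An unconstrained mode (CLI
`--unconstrained`) drops both filters and simply maximises MCR, useful for
seeing which patterns the filters removed.

Known property of the redistribution null: reassignment *with replacement*
clumps events within samples slightly more than Bernoulli-per-gene data
does, so a candidate whose marginal coverage sits in the upper tail of its
own redistribution null can occasionally clear the p < 0.01 gate without
genuine co-occurrence. On the planted-trio benchmark this admitted one
extra decoy in one of eight seeds (the planted pathways themselves were
recovered at every seed); an exhaustive subset search applying the same
test agrees with the greedy result in either case.

## Synthetic cohorts

The generator emits all four input files plus ground truth, fully
deterministic per seed. Background NSY/SY mutations are independent
Bernoulli draws per gene×sample; a small fixed fraction (10%) of NSY
events is emitted as indel/nonsense/splice-site to exercise the max-score
branch, and 10% of missense events are left out of the impact table to
exercise mean imputation. Pathway topologies are random connected graphs
(random spanning tree plus extra edges); covered bases are uniform in
[5·10⁴, 2·10⁵]; missense impacts are clipped-normal within configured
bounds.

Planted structure: a collaborative group marks a Bernoulli(target) block
of samples and gives every member pathway ≥1 NSY mutation there, spread
over *randomly chosen* member genes — embodying the premise that a driver
pathway need not be dominated by one gene, and what makes the dominance
and MCR benchmarks meaningful. Dominated pathways receive all their
coverage through one designated gene (their other members are excluded
from the NSY background so the planted pattern is clean).

Presets: `null` (200 pathways × 200 samples, no structure, for
calibration; pathways may overlap in genes, as real pathway collections
do), `planted_trio` (3 pathways co-mutated in 60% of 500 samples, 7
decoys), `dominated` (72% single-gene pathway plus an honest pair), and
`breast_like` (four groups of 93/57/224/124 samples with group-specific
planted sets). The structured presets use gene-disjoint pathways so decoys
are genuinely independent. Background rates (0.02–0.05 NSY per gene per
sample) are chosen so that per-pathway coverage lands in the 20–40% band
typical of pathway-level summaries of real cohorts; panels here are tens
to hundreds of genes rather than exome-wide, so per-gene rates are
correspondingly higher than exome-wide per-gene rates.

What the synthetic benchmarks do **not** show: robustness to mutational
signatures and context-dependent rates, copy-number and epigenetic
alterations, gene-length and replication-timing biases in the background
model, or inter-gene correlation beyond the planted blocks. Passing them
demonstrates internal correctness and calibration, not field performance.

## Determinism and seeds

Every stage derives its generator from the master seed via
`blake2b(master_seed:label)`, and per-group runs hash the group name into
the label, so adding a group never perturbs another group's results. Two
runs with the same master seed are byte-identical on disk; the resolved
configuration is persisted next to the results and reproduces the run when
fed back.

## Problem sizes used in checks

The packaged verification runs use 200-permutation to 1000-permutation
settings on cohorts of 120–500 samples and 5–200 pathways, sizes at which
every oracle (exhaustive subset search, full 2^(n·m) pattern sweeps, exact
enumeration of the redistribution null) is itself computable; the
production defaults (5000 permutations, top 60 of 200 pathways) match the
intended analysis scale.
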