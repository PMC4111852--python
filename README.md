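# mudpac

Identification of **collaborative driver pathways** from somatic mutation
cohorts.

Most driver mutations are individually rare, which makes gene-level
frequency statistics fragile: different cohorts implicate different genes.
The processes disrupted during transformation are far more reproducible
than the individual mutations that disrupt them. `mudpac` therefore works
at the pathway level, in two steps:

1. **Mutational pathway enrichment.** Every gene receives a ranking score
   combining a *Mutation Factor* and an *Interaction Factor*, and each
   pathway is tested for concentration of high-scoring genes with a
   weighted Kolmogorov–Smirnov (WKS) permutation test.
2. **Collaborative set search.** Among the top enriched pathways, a greedy
   algorithm assembles the set of pathways that are *co-mutated* in the
   largest fraction of samples, rejecting pathways whose coverage is the
   work of a single hypermutated gene and pathways whose co-occurrence
   with the current set is not statistically significant.

Intended users: cancer-genomics analysts with somatic mutation calls (MAF),
pathway definitions with topology, per-gene sequencing-coverage totals and
per-mutation functional-impact scores.

## The model

For gene *i* in sample *j*, the mutation matrix holds impact-weighted,
coverage-normalised burdens, split into non-synonymous (NSY) and synonymous
(SY) rows:

```
M_ij_* = Σ_mutations (bases_mutated × impact) / covered_bases(i)
```

Impact scoring: indels, nonsense and splice-site variants take the maximal
attainable impact score; silent variants the minimal one; missense variants
their own computed score (cohort-mean missense score when none exists).

**Mutation Factor** — the NSY/SY contrast, weighted by the event-count
ratio:

```
MF_i = (N_i_NSY / max(N_i_SY, 1)) · (1/m) Σ_j (M_ij_NSY − M_ij_SY)
```

**Interaction Factor** — for gene *i* in pathway *P*, the average pairwise
influence over the other members, where each pair combines shortest-path
distance *d*, exclusive pairwise coverage *C* and mutual exclusivity *ME*:

```
f_ij = (C_ij · ME_ij) / (1 + d_ij),      f_ij = 0 if i,j disconnected
IF_i = (1/(|P|−1)) Σ_{j≠i} f_ij · 1[f_ij ≥ α],   floored at α  (α = 0.005)
```

**Ranking score** `exp(MF_i) · IF_i` (positive, increasing in both
factors). Genes outside a pathway get imputed scores drawn from the
cohort-wide background score distribution, gated by the pathway's fraction
of α-passing members. The WKS statistic is the maximum deviation (MD)
between the score-weighted CDF of member genes and the uniform CDF of
non-members along the ranked list; its null distribution comes from
shuffling each member gene's mutation profile across samples (5000
permutations by default), and `FDR = p·m/k` corrects across the *m*
pathways.

**Step 2.** A pathway *covers* a sample if ≥1 member gene is
non-synonymously mutated there; the *Maximal Coverage Rate* (MCR) of a set
is the fraction of samples covered by *every* member. Greedy selection
adds, at each step, the candidate maximising the joint MCR, subject to
(i) MCR ≥ top single-gene rate + 5% (dominance filter — a 72% pathway
driven by a 72%-mutated TP53-like gene is rejected) and (ii) a mutation
redistribution permutation p < 0.01 against the already-selected set.

## Worked example

Generate a synthetic cohort with known ground truth and run both steps.
The `dominated` preset plants a co-mutated pathway pair plus one pathway
whose entire 72% coverage flows through a single gene:

```bash
mudpac simulate --preset dominated --seed 4 --out-dir demo/data
# wrote 1478 mutations over 300 samples and 6 pathways to demo/data

mudpac run \
  --maf demo/data/cohort.maf --pathways demo/data/pathways.txt \
  --coverage demo/data/coverage.tsv --impacts demo/data/impacts.tsv \
  --out-dir demo/out --seed 1 \
  --n-perm-enrichment 1000 --n-perm-collab 2000
# selected 2 pathways (MCR 0.495) -> demo/out
```

`demo/out/collaboration.tsv` records the greedy trajectory:

```
step  pathway_id  mcr_after            p    max_gene_rate
1     PW001       0.6020066889632107   nan  0.14046822742474915
2     PW002       0.49498327759197325  0.0  0.13043478260869565
```

Reading: PW001 covers 60.2% of samples and its busiest gene only 14%, so
it passes the dominance filter and seeds the set (the first pathway has no
partner, hence no collaboration p). Adding PW002 keeps 49.5% of samples
jointly covered — far above what random redistribution of PW002's
mutations achieves (p < 1/2000) — so the pair is accepted. The planted
truth (`demo/data/truth.json`) is exactly {PW001, PW002}; the
single-gene-dominated pathway PW000 is enriched in step 1 but rejected in
step 2 because its MCR cannot exceed its top gene's rate by 5%.

Per-subtype analysis (`mudpac compare-groups --groups samples.tsv ...`)
runs the whole pipeline independently per sample group and tabulates
shared versus group-specific pathways. `--unconstrained` switches off both
step-2 filters for diagnostic comparison.

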