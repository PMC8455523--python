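# Methods

## The statistic: connectivity across a sex-composition gradient

`coexsweep` asks whether a gene's position in the co-expression network
depends on the sex composition of the population the network is estimated
from. The network statistic is WGCNA-style whole-network connectivity:
from a genes × samples matrix of log2(TPM + 1) values restricted to one
population, the Pearson correlation `r_ij` between every gene pair is
soft-thresholded into an unsigned adjacency `a_ij = |r_ij|^β` with β = 5,
and each gene's connectivity is `k_i = Σ_{j≠i} a_ij`. Soft thresholding
suppresses weak correlations (at β = 5 a correlation of 0.5 contributes
0.03, a correlation of 0.9 contributes 0.59), so `k_i` measures membership
in strongly co-expressed groups rather than diffuse correlation. A signed
adjacency `((1 + r)/2)^β` is available behind a flag; the unsigned form is
the default and the one every test exercises.

One *gradient sweep* fixes a population size `n` (by default
`min(n_females, n_males)` after filtering, so every population is equally
powered), draws `n` random females as population 0, and then repeatedly
removes one remaining female (uniformly at random) and adds one unused
male from a random male subsample of size `n`, giving `n + 1` populations
from all-female to all-male that differ by one sample per step. Computing
`k` on every population yields a genes × (n + 1) trajectory. The `n + 1`
ordered populations are split into five contiguous blocks — column `i`
goes to block `⌊5i/(n+1)⌋`, so block sizes differ by at most one — and
each block is summarized by the per-gene median connectivity, Q1
(female-most) through Q5 (male-most). The bias statistic per gene is

    log2fc = log2(Q5 + ε) − log2(Q1 + ε),   ε = 1e−6.

Positive values mean higher connectivity in male-dominated populations. A
gene is *called* in one sweep when |log2fc| strictly exceeds 1 (a two-fold
connectivity change between the extremes). The sweep is repeated
`n_iterations` times (default 100) with fresh random subsamples and
orders; a gene is *sex-biased* when called in at least `min_calls`
iterations (default 20, inclusive), with the direction decided by majority
vote among its calling iterations. Ties are reported as `none` with a
warning rather than broken arbitrarily; across the repeats a genuinely
biased gene calls in one direction essentially always, so ties only arise
for marginal genes.

The ratio rather than the difference of the extreme quintiles is used
because connectivity spans orders of magnitude between correlated and
uncorrelated genes; a log ratio makes the threshold scale-free. The ε
pseudocount only matters when both medians are essentially zero (a gene
uncorrelated everywhere), where it correctly forces log2fc → 0; it is far
below the connectivity of any gene with even one partner at |r| ≈ 0.4.

## The calibration null

The question "is the count of threshold-passing genes larger with a sex
gradient than without one?" needs a null that reproduces every property
of the sweep except the sex ordering. Two naive constructions fail in
opposite ways:

* Drawing each null population independently from the pooled samples
  destroys the sweep's chained structure. Gradient populations share
  `n − |j − k|` samples between steps `j` and `k`, so a gene's
  connectivity trajectory is a strongly autocorrelated random walk and
  the extreme-quintile medians diverge even without any sex effect.
  Independent draws average this walk away, so the null count collapses
  toward zero and the comparison is anti-conservative.
* Splitting the pool into two random halves and sweeping between them
  preserves the chained structure but re-introduces a composition
  gradient by accident: the male fraction of the two halves differs with
  a standard deviation of several percent, and β = 5 amplifies even a
  10 % composition trend into |log2fc| > 1 for genuinely sex-dependent
  genes. On data with strong sex structure such a null inherits part of
  the signal it is meant to calibrate away.

The null implemented in `run_null` therefore keeps the gradient's exact
plan topology — `n + 1` chained populations, only original members are
removed, in uniformly random order — but makes every population
sex-balanced: the starting population holds `⌊n/2⌋` random females and
the rest males, and each removed sample is replaced by an unused sample
of the *same* sex. No sex gradient exists by construction, and because
the population-overlap structure is identical to the gradient's, the two
produce identically distributed threshold-passing counts when samples
are exchangeable (no sex structure in the data). Both properties are
verified empirically in the test suite: on unstructured data the gradient
count falls inside the null 95 % interval at the expected rate, and on
data with planted sex-dependent modules every gradient iteration's count
exceeds the null's 97.5th percentile.

The interval bounds are the 2.5th/97.5th percentiles of the per-
permutation counts, estimated with the median-unbiased quantile estimator
(Hyndman–Fan type 8). With 10–25 permutations the default linear
interpolation is inward-biased in the tails; the median-unbiased form is
the standard recommendation when the distribution shape is unknown and is
slightly conservative, which is the right direction for an interval used
as a calibration reference. (The evidence-score quantile used for
association filtering, below, deliberately stays with plain linear
interpolation.)

## The menopause variant

Within females only, the same machinery runs over the age dichotomy
< 50 vs ≥ 50 years (age is recorded in decades; a decade belongs to the
younger group when its lower bound is below 50). Group A (premenopause)
plays the role of females, group B (postmenopause) of males; direction
labels become `premenopause`/`postmenopause`. When a list of sex-biased
genes is supplied, the overlap fraction |supplied ∩ affected| / |supplied|
reports how much of the sex-biased signal is attributable to the
menopause dichotomy.

## Downstream statistics

*Over-representation.* Enrichment of a biased-gene list in a GMT
collection is the exact hypergeometric upper tail
`P(X ≥ k)` for overlap `k`, query size `q`, set size `m` and universe
`N`, with the universe defined as the genes that passed the expression
filters (the tested genes, not the genome). Significance is the raw
`p < 0.05`; a Benjamini–Hochberg column is emitted for reference but does
not drive the flag, so the output mirrors the conventions of standard ORA
tooling while leaving stricter control to the caller.

*Association filtering.* Gene–disease tables with evidence scores are
reduced in two steps: keep diseases annotated with at least 100 genes,
then keep rows scoring at or above the 90th percentile (linear
interpolation) of the retained table.

*Overlap permutation test.* Whether a query set (e.g. sex-biased disease
genes) overlaps a target list (e.g. FDA-approved drug targets) more than
chance is tested by drawing size-matched sets from a comparator pool (the
non-biased analyzed genes) without replacement, 10,000 times by default.
The headline p-value is upper-tail with add-one correction,
`(1 + #{null ≥ observed})/(n_perm + 1)`, whose floor halves when the
permutation count doubles; the raw proportion of null overlaps below the
observed one is also reported as a diagnostic, since that quantity is
sometimes quoted directly in the literature even though it grows with
the observed overlap.

## Input filters

Samples require RIN strictly above 6.0 (missing RIN excludes the sample
with a warning). A tissue is analyzable when at least 80 samples of each
sex survive the RIN filter. Genes enter the analysis when their
log2(TPM + 1) profile has mean ≥ 1 and unbiased (n − 1) variance ≥ 1
across the retained samples; both moments are computed on the log scale
so the two cuts are mutually consistent, and the pseudocount of 1 keeps
zero TPM finite. PCA QC ranks genes by log-scale variance, takes the top
1000 (capped at the gene count) and reports per-sample scores on the
first two components of the centered matrix; it informs visual QC only
and feeds nothing downstream.

## The synthetic-data generator

The generator emulates exactly the statistical structure the sweep is
designed to detect, on the TPM scale the filters expect. Each planted
module has one latent factor per sample; a module gene's latent value in
sample `s` is

    z = sqrt(ρ_eff)·f_s + sqrt(1 − ρ_eff)·ε,

with `ρ_eff = rho_on` when the sample matches the module's target group
(`male`, `female`, `both`, or `premenopause_female` = females in decades
below 50–59) and `rho_off` otherwise, so the population correlation of
two module genes in the active group is `rho_on`. TPM values are
`2^(μ_g + σ_g·z) − 1` floored at zero, which makes log2(TPM + 1) recover
the Gaussian latent scale exactly whenever `μ_g + σ_g·z ≥ 0`. Background
genes are independent noise; DE-only genes are independent noise plus a
sex-specific mean shift (default 1 log2 unit, split ±0.5 between the
sexes), planting differential expression with no co-expression structure
so the two signals can be shown to be distinct.

Defaults: `base_log2_mean = 6` with per-gene jitter of ±1, and
`gene_log2_sd = 1.5`. These keep every generated gene ~4 standard
deviations above the zero floor (so truncation is negligible and the
log2 moments are as designed) and clear the mean ≥ 1 / variance ≥ 1
filters with wide margin — the generator's contract is that planted genes
are never silently dropped by the pipeline's own filters. RIN is drawn
from U(6.5, 9.5) so all synthetic samples pass the quality filter; age
decades are sampled independently of sex with GTEx-like adult weights
(20s 7 %, 30s 8 %, 40s 16 %, 50s 31 %, 60s 33 %, 70s 5 %) so the
menopause dichotomy is populated realistically.

What the generator does *not* emulate: count-level sampling noise
(TPM values are log-normal, not from a read-count model), tissue
composition and cell-type mixtures, covariate confounding beyond sex and
age, library-size artifacts, and correlated module overlap (each planted
gene belongs to exactly one module). Passing tests therefore demonstrate
that the procedure recovers group-dependent correlation structure of the
planted form and strength — not that any particular biological dataset
contains such structure.

## Problem sizes used in the test and acceptance runs

The recovery experiments use two 25-gene modules (male- and
female-targeted, `rho_on = 0.9`, `rho_off = 0`) plus 250 background genes
with 80 samples per sex and 25 sweep iterations; the DE-separation
variant adds 40 mean-shift-only genes. Calibration uses 20 datasets of
100 independent genes with 40 samples per sex, 10 gradient iterations and
10 null permutations each. The menopause recovery uses one 25-gene
premenopause module among 75 background genes, 120 females split evenly
between the 40s and 50s decades, population size 45 and 25 iterations.
These sizes make each full run complete in seconds while leaving the
recovery and calibration margins wide.

## Numerical and degenerate-input conventions

Zero-variance genes within a population get correlation 0 to every
partner (not NaN), so adjacency sums stay finite; the event is logged.
Correlations are clipped to [−1, 1] before powering to absorb floating-
point excursions. The adjacency diagonal is zero, so `k ∈ [0, G − 1]`.
Empty queries, empty tables and undersized groups raise immediately with
the violated bound named. All randomness flows through
`numpy.random.Generator` seeded from a single configuration seed; the
consistency run spawns one child seed per iteration through
`SeedSequence`, which makes iterations independent and the whole
procedure bit-reproducible.

## Known limitations

Whole-network connectivity is the only tracked co-expression scalar;
intramodular connectivity, topological overlap and eigengene-based
summaries are out of scope. The bias call is threshold-based, not a
per-gene p-value: the permutation null calibrates the *count* of passing
genes, not individual genes. Direction by majority vote discards the
size of the majority. The generator's single-factor modules cannot
express partial overlap between modules or sex-dependent *sign* flips of
correlation. With very small populations (< ~20 samples) the correlation
estimates are noisy enough that the per-iteration false-call rate on
independent genes becomes substantial; the consistency rule absorbs most
but not all of it, which is why the defaults require both ≥ 80 samples
per sex and 20 of 100 iterations.
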