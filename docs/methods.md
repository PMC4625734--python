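# Methods

## Read model and posterior

The quantity inferred per sample is π, the probability that a read mapping
to the *SMN1*/*SMN2* paralog-defining positions originates from *SMN1*.
Given r total SMN reads and a (scaled) *SMN1* count D′, the model is the
conjugate beta-binomial update

    D′ ~ Binomial(r, π),  π ~ Beta(α, β)  ⇒  π | D′, r ~ Beta(α + D′, r − D′ + β).

The carrier probability is the posterior CDF at the threshold 0.38 — the
carrier-compatible ratio 1:2 gives π = 1/3, and the threshold adds a 5 %
type-I margin. The default prior is Jeffreys (α = β = ½); the uniform
prior (1, 1) is selectable and differs negligibly at realistic read counts.
Assumptions worth keeping in mind: reads at the six positions are treated
as independent Bernoulli draws (no fragment-level duplication structure),
and alignment is taken to be unbiased between the paralogs.

Key defaults:

| parameter | default | meaning |
|---|---|---|
| α, β | ½, ½ | Beta prior shapes (Jeffreys) |
| carrier threshold | 0.38 | upper bound on π for a carrier-compatible ratio |
| credible level | 0.95 | mass of the equal-tailed posterior interval |
| ε | 0.10 | flank-vs-exon-7 proportion consistency tolerance |
| control-gene filter | 5th pct, 10 % | within-sample percentile, failure fraction |
| control genes K | 2 × 10 | top-10 per stability criterion |
| recommended reads | 350 | advisory coverage floor (90 % carrier sensitivity) |

### Degenerate inputs and numerical choices

* r = 0 is legal: the posterior equals the prior, the category is computed
  as usual (always "possible"), and the report carries the zero counts.
  Every sample is scored regardless of coverage; r < 350 only sets an
  advisory flag, because low coverage widens the interval rather than
  biasing the estimate.
* D′ is a real pseudo-count (θ̂·D); the Beta posterior accepts it without
  rounding.
* Credible intervals are equal-tailed (central) quantile intervals, not
  highest-posterior-density: the choice was genuinely open, and central
  intervals are reproducible without optimisation and match the
  interval-vs-threshold categorisation rule. An interval that touches the
  threshold exactly counts as spanning it ("possible").
* The binary carrier call is strict: probability exactly ½ is a
  non-carrier.
* All Beta CDF/quantile evaluations go through scipy's regularised
  incomplete beta functions; no sampling is involved in the calling path,
  so cohort results are bit-reproducible.

## ε-rule pooling

Per-locus proportions π̂_ℓ = D_ℓ/r_ℓ are undefined at zero depth. The
pooling rule sums depths over the three loci only when both flanking
proportions are defined and within ε = 0.10 (inclusive) of the exon-7
proportion. An undefined flank cannot certify consistency, so it fails the
rule and the exon-7 locus is used alone; an undefined exon-7 proportion
falls through to that locus's zero counts (the r = 0 path). Raw integer
depths are summed without per-locus normalisation.

## Coverage scaling

z_ki = (cov_SMN1 + cov_SMN2)/cov_k for control gene k is normalised by its
cohort mean z̄_k; θ̂_i is the mean of z_ki/z̄_k over the K selected genes,
capped at 1 (conservative: scaling can only lower the *SMN1* count). The
cap means scaling never manufactures carriers out of high-coverage
samples; it only rescues reduced-copy samples whose read ratio looks
canonical.

Control genes are selected among candidates that pass a recurrent-low-
coverage filter — a gene fails in a sample when its coverage is strictly
below the (default 5th) percentile of that sample's candidate-gene
coverages, and is removed when it fails in ≥ 10 % of samples. The
percentile is computed within sample across genes; the phrasing was open
to interpretation and this reading is parameterised. Survivors are ranked
by coefficient of variation (sample SD / mean) of coverage and of z_ki;
the top ten of each ranking are merged, with round-robin backfill to 20
distinct genes when more than 20 survive. CV ties break by gene id for
determinism. z̄_k is computed over all samples in the analysed cohort
(cohort mode); reference mode substitutes externally supplied z̄ values
and a fixed control-gene list, making per-sample results independent of
cohort composition — useful for single samples, with the caveat that the
procedure was designed cohort-wide.

With a single-sample cohort z̄ equals the sample's own z and θ̂ is
identically 1; this is flagged as uninformative.

## Simulator

For a grid of (r, π), D is drawn Binomial(r, π) (1000 replicates by
default) and the posterior carrier probability is averaged — the average of
P(π ≤ 0.38 | D, r) over draws, not the fraction of draws classified as
carriers. θ̂ is held at 1: the simulation isolates read-sampling noise
from coverage normalisation. π ∈ {0, 1} is degenerate and computed exactly
from the single possible outcome. Each grid point derives an independent
random substream from (seed, r, π), so results do not depend on grid shape
or evaluation order. At 1000 replicates the Monte-Carlo standard error of
the mean is at most 0.016; point comparisons in the tests use a 0.02
absolute tolerance.

## Population statistics

Carrier frequencies are compared with published values by the two-sided
exact binomial test in the minimum-likelihood convention (sum of P(X = x)
over outcomes no more likely than observed — the convention of R's
`binom.test` and `scipy.stats.binomtest`), with exact Clopper-Pearson
confidence intervals. Note that a published comparison frequency printed
to two significant figures limits how precisely the p-value itself can be
reproduced: perturbing p₀ within its rounding interval moves the p-value
by a few thousandths, which is the agreement the tests require. MLPA
*SMN1*:reference ratios are categorised with the standard 0.7 (loss) and
1.3 (gain) thresholds; the concordance table joins sequencing and MLPA
calls on sample id and reports unmatched ids rather than failing.

## Synthetic cohorts

The generator draws, per sample and locus, a Poisson read total with mean
(total SMN copies) × (depth per copy), allocates *SMN1* reads binomially
with the genotype's true π, and draws gene-level coverages from gamma
distributions (CV = `noise`) whose means are proportional to copy number
— the simplest generative model consistent with the read model above.
Defaults: 125 reads per copy per locus (≈ 500× per locus for a canonical
sample, comfortably above the 350-read advisory), control-gene mean
coverage 100×, coverage CV 5 % (a realistic residual for exome-scale mean
coverages), 30 candidate control genes. `noise = 0` switches to rounded
expectations, giving a deterministic limit for structural assertions.
`pi_override` decouples the read proportion from the copy ratio to emulate
recombinant/hybrid SMN alleles — the genotype class where a carrier's
reads split ~1:1 and only coverage scaling reveals the copy loss.

What the generator does **not** emulate: alignment artifacts, reference
bias, GC-dependent coverage, correlated (library-size) coverage
variation, or read-level sequence content (the mini-BAM writer emits
placeholder bases — only positions and flags are meaningful, and its reads
are kept shorter than the 49-bp spacing of the closest loci so planted
depths stay independent). Passing end-to-end tests therefore demonstrate
the statistical machinery under the model's own assumptions, not
robustness to real-data artifacts.

Two cases sit exactly at structural margins and are worth knowing about:

* A 3-total-copy sample with a 1:1 read split scales to π̂′ → 0.375, just
  below the 0.38 threshold; the binary rescue is asserted in the
  deterministic limit, since a noisy draw can legitimately land on either
  side. The 2-total-copy analogue (θ̂ → ½, π̂′ → 0.25) is rescued
  decisively.
* Rank correlation between π̂ and π̂′ is high only when θ̂ is a small,
  stable correction: independent coverage jitter on the scaling factor
  reshuffles ranks within genotype groups regardless of its magnitude
  (rank statistics are scale-free), and scaling intentionally maps
  genotypes with equal *SMN1* copy number (e.g. [2:1] and [2:2]) toward
  the same scaled proportion. The rank-correlation test therefore uses a
  mostly-canonical cohort with 1 % coverage CV, emulating the stability
  that control-gene selection achieves on exome-scale candidate pools.

## BAM depth extraction

The adapter counts aligned, non-duplicate, non-secondary,
non-supplementary reads having an aligned base at each 1-based position,
with configurable mapping- and base-quality floors (default 0, i.e.
permissive, since the upstream depth-tool settings this mirrors are a
matter of site policy; all filters are logged). Contig naming (chr5 vs 5)
is resolved by trying both. The primary input path remains the tabular
depth file: the statistics, not alignment handling, are the point of the
package.

## Known limitations

* Silent "2+0" carriers (two *SMN1* copies on one chromosome) are
  undetectable from read ratios; no phase information is used.
* Only biallelic paralog-defining positions are modelled; a
  multinomial-Dirichlet generalisation would be needed for loci with more
  than two alleles.
* Cohort mode couples samples through z̄_k; removing a sample perturbs the
  others' θ̂ slightly.
* The method reports carrier probability, not integer *SMN1*/*SMN2* copy
  numbers.
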