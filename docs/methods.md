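# Methods

## The problem

Genomic imprinting is the parent-of-origin–dependent expression of the two
alleles of a gene. Detecting it from RNA-seq of reciprocal F1 hybrids
requires separating a true parental bias from (i) the estimation
uncertainty of allele-specific expression levels, (ii) systematic effects
of the experimental factors (cross direction, sex, age), and (iii)
biological variability across animals. `braim` models all three
explicitly, per transcript.

## Model

Inputs are per-sample, per-allele posterior draws of expression in TPM
(e.g. from MMSEQ-style Bayesian quantification). For sample *j* the
response is the posterior mean of the log allelic contrast

    y_j = mean_s [ log(TPM_j^(s)(pat) + c) − log(TPM_j^(s)(mat) + c) ],

with the posterior variance of the same per-draw contrast (denominator
S−1) carried forward as a known measurement-error variance e_j. Before
the contrast, any sample whose posterior median TPM falls below the floor
c = 0.01 has all draws replaced by c — the minimal measurable expression —
so the log is always defined. The response is divided by its
across-sample standard deviation (and e_j by its square, since variances
transform with the square of a scale factor) so coefficients are
comparable across transcripts; the scale factor is retained to map the
parental coefficient back to the natural log scale.

The hierarchical model per transcript is

    y' | z        ~ MVN(z, E),          E = diag(e)     (measurement)
    z  | β, σ²    ~ MVN(Xβ, σ² I)                       (biology)
    β_i | σ², δ_i ~ N(0, σ² (τ c^{δ_i})²)               (spike-and-slab)
    δ_i ~ Bern(p),  σ² ~ IG(ν/2, νλ/2).

X has an all-ones intercept column carrying the parental effect (the
response is already the paternal−maternal contrast) and ±1-coded columns
for cross (F1i = +1), sex (male = +1) and age (P8 = +1). δ_i selects
between a narrow "spike" normal (effect absent) and a slab widened by the
multiplier c; the posterior mean of δ_i is the effect's posterior
probability (PP), and an effect is called significant at PP > 0.95.

All four conditionals are conjugate and sampled by a Gibbs sweep
z → β → σ² → δ:

* z: diagonal Gaussian, precision 1/e_j + 1/σ², elementwise;
* β: MVN with covariance σ² (XᵀX + D⁻¹)⁻¹, D = diag((τ c^δ)²);
* σ²: IG with shape (n + p + ν)/2 and scale ½[νλ + ‖z − Xβ‖² + βᵀD⁻¹β];
* δ_i: independent Bernoulli with odds p/(1−p) divided by the spike/slab
  density ratio at β_i, computed in log space.

Defaults: τ = 0.1, c = 4.25, ν = 2.5, p = 0.1, and λ from the closed form
λ = (2·var(y′)/5)(1/ν)(ν/2 − 1), which is 0.04 at ν = 2.5 since the
scaled response has unit variance. Chains run 10,000 sweeps with 1,000
burn-in.

## Numerical choices

* Initialization: z = y′, β = 0, σ² = 1, δ = 0 — a data-centered,
  prior-neutral start whose transient the burn-in absorbs.
* Exactly-zero measurement variances (floored transcripts) are clamped to
  1e−8 so E stays invertible; the statistical effect is negligible.
* Bernoulli probabilities are clamped to [1e−12, 1 − 1e−12]; density
  ratios are computed in log space.
* δ takes only 2^p values and XᵀX is fixed, so the Cholesky factors of
  XᵀX + D⁻¹ for every δ configuration are computed once per transcript;
  each sweep is then a handful of small vector operations. The standalone
  conditional samplers implement the identical distributions and both
  paths are validated against an exact enumeration oracle.
* Each transcript gets an independent RNG stream seeded by (global seed,
  CRC32 of its id), so results are order-independent and reproducible.
* A transcript whose response is constant across samples (sd = 0) cannot
  be scaled and is skipped with a warning.

## Effect interpretation and calling

The parental coefficient mapped back to the unscaled log response, β̂, is
the mean log paternal/maternal expression ratio; the paternal fraction of
total expression is the logistic exp(β̂)/(1 + exp(β̂)), the maternal
fraction its complement, and the parental bias the larger of the two.
(Point estimate: the posterior mean; medians are available.)

A transcript is called imprinted when (i) its combined-ages fit has
parental PP > 0.95; or (ii) it is expressed exclusively in one age group
— operationalized as every sample of the other age floored — and that
age's fit (which drops the age column) has parental PP > 0.95; or (iii)
the combined fit has age PP > 0.95 and either single-age fit has parental
PP > 0.95. Exclusively-expressed transcripts are judged by their age fit
alone, since the combined model presumes expression at both ages.
Optional single-allele refits (response = one allele's log level)
classify whether the preferred or the non-preferred allele drives an age
effect.

## Transcript combining

Isoforms of one gene that the reads cannot distinguish show strongly
anti-correlated posterior draws. For every same-gene, same-allele pair
the per-sample Pearson correlation of draws is averaged over samples;
pairs below −0.25 on *both* alleles are merged — most negative mean
first, correlations recomputed after each merge, iterating until no pair
qualifies. Merged expression is the elementwise sum of the members'
draws: under read-assignment ambiguity the summed abundance is the
well-identified quantity, and summing conserves the gene's total
expression while shrinking the combined unit's posterior spread.
Requiring both alleles keeps combined units identical across alleles.

## Cluster decay

Each gene is represented by its isoform with the highest parental PP
(ties: larger |β̂|, then id). Chromosomes are scanned 5′→3′; a gene
chains into the current cluster when its start lies within 1 MB of the
previous gene's end. Genes with bias above 85:15 are candidate centers;
physically consecutive candidates merge into one center interval;
clusters with several center groups split into sub-clusters at midpoints
between adjacent groups (1 MB flanks at the extremes). A member's
distance is from its start site (strand-normalized: end coordinate for
antisense genes) to the nearest edge of its center interval, zero
inside; genes farther than 1 MB are dropped, and members of centerless
clusters carry undefined distances and are excluded from the regression.
The decay estimate is a pooled OLS fit of bias on distance over
non-center members, with the usual t-test on the slope. The distance
anchor (start-to-edge) is a design choice; start-to-start is the obvious
alternative and changes distances only for wide center intervals.

## Sensitivity analysis

Each hyper-parameter is perturbed one at a time over a fixed grid (τ:
0.005, 0.01, 1, 2; c: 1.7, 3.4, 5.3125, 10.625; ν: 5, 12.5, 25, 50; λ:
0.002, 0.004, 0.4, 0.8; p: 0.2–0.5), refitting a 10% transcript
subsample drawn once. Transcripts significant under the unperturbed fit
are the ground-truth positives and the perturbed parental PPs are scored
by rank AUC. The same per-transcript MCMC seeds are reused across
perturbations so ranking changes reflect the hyper-parameters, not
Monte-Carlo noise; the unperturbed self-comparison is therefore exactly
AUC = 1.

## Synthetic data

The generator mirrors the model's assumptions: per transcript and sample
the true log contrast is d_j ~ N(x_jᵀβ_true, σ²_true); the two allelic
log levels sit symmetrically at base ± d_j/2 so bias is unconfounded
with overall expression; each allele emits S lognormal draws
(exp(log-level + N(0, meas_sd²)) − c, clamped at 0) emulating posterior
spread. Defaults for recovery studies follow the fitted model's study
design: 48 samples (6 per cross×sex×age block), S = 100 draws,
σ²_true = 0.25, meas_sd = 0.1, and 1 in 10 transcripts imprinted with
|parental effect| drawn uniformly from [1, 3] in alternating sign —
effects of that size correspond to biases of roughly 73:27 to 95:5,
the moderate-to-strong range where calls should be reliable. A helper
simulates read-sharing isoform pairs (a random per-draw share of a
near-constant total) to exercise the combiner.

What the generator does **not** emulate: MMSEQ's full cross-isoform
posterior correlation structure, non-lognormal posterior shapes,
library-size or mapping biases, allele-specific mapping artifacts, and
expression-correlated bias (an optional expression effect can be added
via the spec's beta fields). Passing recovery tests therefore show the
inference is correct *under the model's own assumptions*, not that those
assumptions hold for any particular real dataset.

## Problem sizes and known limitations

Simulation-based checks use a 500-transcript cohort (50 imprinted) at
n = 48 with full-length 10,000-iteration chains; sampler-exactness checks
use n ≤ 6, p ≤ 2 problems where the posterior is computable by
enumeration. The published full-cohort quantities (candidate counts, the
observed bias distribution, the cluster-decay and synteny p-values)
require the original sequencing data and annotations and are out of
scope; module invariants (expression conservation under combining,
allele-swap symmetries, cluster partition properties, ROC invariances)
stand in for them. Other limitations: no convergence diagnostics beyond
the fixed burn-in; no FDR control across transcripts (a fixed PP cutoff
is the design); the combining step is quadratic in isoforms per gene;
and the decay regression pools clusters with a single shared slope.
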