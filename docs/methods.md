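# Methods

## Design and data model

The analysis targets cohorts of monozygotic (MZ) twin pairs partitioned
into disease-discordant (PDC: one affected cotwin), disease-concordant
(PCC: both affected) and healthy-concordant (HCC) classes; the default
design is 6 PDC + 4 PCC + 4 HCC pairs (28 individuals). The primary
observable at a heterozygous SNP is the pair of read counts
(ref_reads, alt_reads) from 5hmC-enriched sequencing for each
heterozygous individual. Positions follow VCF conventions (1-based);
BED intervals and genomic bins are 0-based half-open; strand is ignored
because 5hmC capture is unstranded.

Candidate sites require at least one read supporting the alternative
allele; the notion of "high-quality read" is resolved upstream by the
variant-aware counting tool, so within this package the rule reduces to
`alt_reads >= 1`. Sites must be present in the WGS genotype call set
with concordant genotypes between cotwins (an MZ identity check), and
only rows from heterozygous individuals are informative. Multi-allelic
records are excluded. The two filters commute and are idempotent.

## Per-individual AShM calls

For each tested (site, individual) with depth ≥ `min_depth` (default 8
reads), the p-value is the exact two-sided binomial probability of an
alt-read split at least as extreme as observed under p = 0.5.
Benjamini–Hochberg correction runs within each individual across that
individual's tested sites, and a call requires q < 0.10. Ties
(alt = ref) and non-significant rows carry direction `none`; calls are
`alt_hyper` or `ref_hyper`. The per-individual statistic is an exact
test rather than a model-based score: it is the minimal choice
consistent with an FDR-controlled per-individual screen, and the mixed
model below is reserved for site-level quantification.

## Site-level quantification model

For site-level inference across individuals,

    y_i ~ Binomial(n_i, sigmoid(beta0 + b_{s(i)} + gamma_i))

with priors beta0 ~ N(0, 3²), gamma_i ~ N(0, sigma_g²),
b_s ~ N(0, sigma_s²) a 2-level mean-zero random status effect, and
half-normal(1) priors on both scales. The beta0 posterior quantifies
the degree of allelic imbalance; credible intervals are empirical
quantiles and the site p-value is the two-tailed posterior tail mass
beyond the null allele ratio of 0.5 (beta0 = 0):
p = min(1, 2·min(Pr(beta0 ≤ 0), Pr(beta0 ≥ 0))). Sites informative in
fewer than two individuals are skipped with a reason code and carry
only their per-individual calls.

## Bayes-factor transition detection

Candidates are sites AShM-significant in at least one PDC individual
and heterozygous in at least `min_pdc_pairs` (default 2) PDC pairs. On
the PDC individuals only,

    M1: logit(p) = beta0 + delta·x_i + gamma_i   (x = +1/2 affected, −1/2 unaffected)
    M0: logit(p) = beta0 + gamma_i

and log BF = log p(y|M1) − log p(y|M0), both marginal likelihoods
integrating over all parameters. The status effect is effect-coded with
a unit-information prior delta ~ N(0, 1) — a proper prior is required
for a finite marginal likelihood, so "fixed effect" here means a
parameter with its own prior rather than an improper flat one. The
delta prior also supplies the Occam penalty that keeps null-site BFs
below 1. BF thresholds 1 (discordant) and 10 (strong) are
configuration-exposed, as are all prior scales; `Priors.scaled(f)`
supports sensitivity reruns at wider/narrower priors.

Independently of the BF, each informative PDC pair votes gain (AShM in
the affected cotwin only), loss (unaffected only), flip (both, opposite
directions) or similar (both same direction, or neither); the site
category is the majority vote, ties giving `unclassified`. The
classifier is deliberately BF-independent: a site can show a large BF
from magnitude changes alone while its pattern stays "similar".

## Inference engine

All models are binomial-logit with Gaussian latent effects. The engine
(`ashmtwin.inference`):

1. integrates the per-individual gamma effects out of the likelihood by
   adaptive Gauss–Hermite quadrature (15 nodes centered and scaled at
   each individual's conditional mode, found by a clipped Newton
   iteration — the integrand is strictly log-concave);
2. finds the mode of the resulting low-dimensional marginal posterior
   (≤ 4 free parameters) by L-BFGS-B with the log-scale parameters
   bounded in [e⁻⁸, e³], and forms a Laplace approximation from the
   numerical Hessian;
3. for marginal likelihoods (Bayes factors), refines by self-normalized
   importance sampling with a defensive 50/50 mixture of two
   multivariate-t(df = 5) proposals — the Laplace component and a
   moment-matched component adapted on a pilot stage with truncated
   weights — so a poor adaptation can never lose the mass the Laplace
   ellipse covers; the log marginal likelihood is the log-mean weight;
4. for site posterior summaries, integrates deterministically on
   adaptively sized tensor grids (61 beta0 × 15 × 15 scale points,
   widened while visible density touches the beta0 boundary). For the
   status model this uses an exact refactorization: conditioning on the
   per-status linear predictors u_s = beta0 + b_s makes the likelihood
   factorize over individuals, and the u-integrals become Gaussian
   convolutions of per-status profile likelihoods evaluated as matrix
   products over a fine u grid (step 0.08, kernels renormalized per
   column so the sigma_s → 0 limit is an exact point mass).

Numerical safeguards: the curvature of the log-marginal in the linear
predictor is clamped non-positive (it is mathematically so by
log-concavity, but floating-point cancellation can flip it at large
scale multipliers); non-positive-definite Hessians are eigenvalue-
clipped. Seeds control all Monte-Carlo draws; the quadrature route is
fully deterministic, which is how the credible-interval stability
contract (endpoints within 0.05 across seeds) is met even for the
weakly identified beta0-vs-status ridge. Both routes are validated in
the test suite against an independent brute-force oracle that uses
trapezoid integration of the gamma effects on a ±14 grid and dense
tensor grids over the remaining parameters.

## Synthetic cohort generator

`simulate_cohort` draws, per site: a scenario from `scenario_mix`; a
random sign; per-pair heterozygosity (cotwins share genotype by
construction); per-(site, individual) gamma ~ N(0, sigma_gamma²); depth
from a negative binomial (mean `depth_mean`, dispersion `depth_dispersion`,
truncated at ≥ 1 read); and alt reads ~ Binomial(depth,
sigmoid(beta0(status) + gamma)). Scenario intercepts (unaffected,
affected), with e = `effect_size` and b = `beta0_stable`:
null (0, 0); stable_ashm (±b, ±b); gain (0, ±e); loss (±e, 0);
flip (±e/2, ∓e/2) — so e is always the |Δlogit| between statuses.

Defaults, chosen once as plausible study conditions: 6/4/4 pairs
mirroring the twin design; depth_mean 40 and dispersion 5 (capture
enrichment is overdispersed; per-site depth at SNPs is not published,
so the NB is a modelling choice); het_prob 0.5 (common SNPs ascertained
as informative are heterozygous in roughly half the pairs);
sigma_gamma 0.3 (mild inter-individual wobble on the logit scale);
effect_size 4 and beta0_stable 2 (clear but not saturated imbalance:
sigmoid(2) ≈ 0.88); scenario_mix 60% null / 20% stable / 7% gain /
7% loss / 6% flip, keeping transitions a minority as in any genome-wide
screen. `simulate_read_intervals` separately emulates regional 5hmC
intensity shared within pairs (log-normal pair effect 0.8, individual
effect 0.4, Poisson reads) for the binned-profile correlation analysis.

What the generator does *not* emulate: reference-mapping bias toward
the reference allele, base-calling error, read-level overdispersion
(beta-binomial noise), linkage between neighboring SNPs, chromatin
context, and real genotype ascertainment. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to those real-data artifacts.

## Downstream statistics

Annotation enrichment uses two-sided Fisher's exact tests on
foreground-vs-background membership counts (point sites against labeled
half-open intervals); the odds ratio is the sample cross-product with a
Haldane–Anscombe 0.5 correction (flagged) when a cell is zero, and
per-label BH q-values accompany the raw p-values. Cross-tissue
combination is fixed-effect inverse-variance meta-analysis on the log
odds ratio (DerSimonian–Laird random effects behind a flag); k
identical studies shrink the standard error by exactly √k.

Direction consistency of an epigenomic mark with hydroxymethylation is
an exact two-sided binomial test of the same/opposite counts against
0.5, sharing its kernel with the AShM test. The labeling rule marks a
(site, feature) pair "same" when the alternative allele's
sign-preserving effect on the mark and its hydroxymethylation side
agree (z > 0 with alt fraction > 0.5, or z < 0 with < 0.5); pairs
failing the e-value < 0.01 effect filter, with zero effect, or at
exactly 0.5 are dropped and logged, since their direction is undefined.

PWM allele scores are additive over positions and min–max scaled to the
motif's attainable range, so scores lie in [0, 1] with the consensus at
exactly 1; JASPAR/MEME counts are column-normalized to frequencies. For
a SNP, every window overlapping it on both strands is scored for each
allele and the maximum taken (the motif-scan convention; mean
aggregation is available), windows with ambiguous bases being skipped.
The effect is |scoreRef − scoreAlt|. The TF screen requires effects at
≥ 3 sites and flags |Pearson r| > 0.5 with p < 0.05, reporting the
correlation sign. Gene-set enrichment matches uppercased identifiers
exactly and accepts either an explicit background gene list or a seeded
random sample from a universe.

Binned profiles tile each chromosome with 500-bp windows every 250 bp;
each read increments every bin it overlaps, and `rhms` is the bin count
per million reads — a depth-normalized relative score valid only for
within-grid comparisons (a simplification of enrichment-based relative
scores; correlations are invariant to the per-sample monotone scaling).

## Problem sizes and open choices

The test suite and the acceptance script run seeded simulations sized
for precise checks at interactive cost: 5,000 null sites × 3 seeds for
FDR control, 200 replicates for flip power, 100 per effect level for BF
monotonicity, 400 sites for classification recovery, 50 sites for
quadrature-oracle agreement, and 60–80 sites for posterior recovery.

Where the analysis design was genuinely open, the package takes these
positions: the per-individual FDR-10% statistic is the exact binomial
test (documented as this package's choice); the site p-value is the
posterior tail area of beta0 rather than a replicated-data predictive
check (the "more extreme than the null allele ratio of 0.5" reading);
BF candidate selection requires one significant PDC individual plus two
informative PDC pairs; and all priors are as stated above and echoed in
the output metadata. Known limitations: no beta-binomial read-level
overdispersion, no reference-bias correction, biallelic SNPs only, and
the Bayes factor — like any Bayes factor — is sensitive to the delta
prior width, which is why it is configuration-exposed with a
sensitivity helper.
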