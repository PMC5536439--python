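# Methods

This note records the models implemented in `admixscan`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical conventions that affect results.

## Admixture tract model

Haplotype ancestry along a chromosome follows a re-draw-from-stationary
Markov kernel (the Li–Stephens-style assumption underlying LAMP-type local
ancestry tools) rather than explicit pedigree recombination: between
markers separated by *d* bp the label is resampled from
{EUR: λ, AFR: 1 − λ} with probability 1 − exp(−G·r·d). This produces
Exponential(G) segment lengths in Morgans, the tract-length distribution
implied by a single admixture pulse G generations ago. Defaults: λ = 0.2,
G = 7, r = 10⁻⁸ per bp per generation — the demographic regime of
African American cohorts in admixture-mapping studies.

Two bookkeeping details matter:

* **Per-individual admixture proportions.** Individual proportions are
  drawn from a Beta with mean λ and SD `lambda_sd` (default 0.10, the
  magnitude of spread reported for global European ancestry in real
  admixed cohorts), shared by an individual's two haplotypes. This is not
  cosmetic: with a single fixed λ, ancestry is independent across
  chromosomes, the genotype covariance is block-diagonal per chromosome,
  and no genome-wide "ancestry axis" exists for PCA to find — the observed
  PC1–θ correlation caps near 0.6. With Beta-distributed proportions the
  correlation is ≈ 0.96, matching the near-unity values reported on real
  data. The marginal EUR fraction at any marker is still λ.
* **Latent re-draw events vs visible tracts.** Only label *changes* are
  visible in the simulated labels; a re-draw that lands on the same label
  is silent. Visible segments therefore have mean length
  1/(2Gλ(1−λ)) ≈ 3.1/G, not 1/G. The simulator records the latent re-draw
  events (`return_redraws=True`) so the 1/G property can be audited
  directly; `mean_tract_length_morgans` uses those, excluding the
  end-censored final segment of each chromosome.

Covariates are independent truncated normals — BMI ~ N(32.5, 8.7²) kg/m²
truncated at 15, age ~ N(41, 13²) years truncated at 18 — moments typical
of an adult fibroid case-control population; the BMI/age joint
distribution of real cohorts (weak positive dependence) is not modelled.
The generative interaction term centers BMI at 25 kg/m² so the baseline
log-odds refers to the normal-weight boundary; fitted models are invariant
to this centering up to reparameterization of the main effects. Default
effect sizes: β_int = ln(0.95) per kg/m² per European copy (the planted
signal the scans must recover), β_LA = 0.15 (consistent with a near-null
ancestry OR at BMI 25 and a protective OR ≈ 0.6 per copy in the obese
range), β_BMI = 0.02, β_age = 0.01, β₀ = −1.2 (≈ 45% cases, the case
fraction of an EMR-derived analytic set).

What the simulator does **not** emulate: genotyping error, phasing,
three-way admixture, sex chromosomes, linkage disequilibrium within
ancestral populations (markers are conditionally independent given
ancestry), EMR phenotyping noise, or confounders beyond age. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to everything real arrays do.

## Quality control

Filters run in a fixed order — sample call rate, marker call rate, MAF,
Hardy–Weinberg in controls — with strict inequalities at the thresholds
(0.95, 0.95, 0.01, 10⁻⁶), so boundary values are retained. HWE uses the
1-df chi-square goodness-of-fit test without continuity correction: at a
10⁻⁶ screening threshold the exact test and chi-square agree on everything
but tiny strata, and chi-square is closed-form testable; monomorphic
markers return p = 1 by convention. On admixed data the Wahlund effect
deflects genotype frequencies from HWE, but at λ = 0.2 and delta ≤ 0.8 the
deflection is far too small to cross 10⁻⁶ at cohort sizes of ~10³.

## Local-ancestry HMM

States are European copy counts {0, 1, 2}; the initial distribution is
Binomial(2, λ); the diploid transition matrix for each inter-marker gap is
the two-haplotype composition of the re-draw kernel; emissions are the
exchangeable binomial mixture of ancestry-specific allele frequencies.
Panel frequencies are floored at [10⁻⁴, 1 − 10⁻⁴] so a single genotype
inconsistent with an extreme panel frequency cannot zero out a chain.
Decoding is the per-marker posterior mode (forward–backward with scaling),
not Viterbi: downstream models consume calls as an additive dosage, so the
marginally most probable copy count is the right summary. Missing
genotypes contribute emission likelihood 1 in every state. Inference uses
the population λ even though individuals vary; the mismatch costs little
because emissions dominate at AIM-level informativeness (accuracy ≈ 0.95
at 140 kb spacing, delta > 0.2).

Marker preparation follows AIM selection first (|Δf| strictly > 0.2), then
greedy windowed LD pruning (window 50, step 5, r² > 0.1 drops the
later-position marker; constant markers have undefined correlation,
treated as 0). Global ancestry divides summed calls by 2M to give a
proportion in [0, 1] — the natural scale for 0/1/2 diploid calls even
though "divide by the number of markers" read literally would give [0, 2].

PCA for stratification adjustment runs on all post-QC markers (PCs are
confounder controls, not ancestry estimates): mean imputation per marker,
centering by 2f, scaling by sqrt(2f(1−f)), scores = left singular vectors
× singular values, sign fixed so each component's largest-magnitude
loading is positive.

## Association models

All models are maximum-likelihood logistic regressions fitted by
Newton/IRLS to gradient infinity-norm < 10⁻⁸ (≤ 50 iterations), with the
inverse observed information as covariance. The IRLS core is written
directly in numpy because the permutation layer refits on the order of
10⁵ models; its estimates, standard errors and log-likelihoods are
cross-checked against an independent maximum-likelihood implementation in
the test suite, and against the closed-form 2×2 log-OR/Woolf-SE oracle.
Guards: outcomes with one class are rejected; aliased columns are detected
by a deterministic keep-earliest Gram–Schmidt sweep and dropped (a reported
term perfectly collinear with a dropped column is flagged `aliased`);
|β| > 15 on the logit scale is treated as separation and the fit flagged
non-converged with no estimate emitted.

Interaction p-values are two-sided Wald (the convention of the standard
GWAS tools this mirrors); the likelihood-ratio test is used only for the
3-df group × BMI-category interaction, where the full model adds
group × category products to a reduced model with category and group main
effects. BMI categories are left-closed ([25, 30), [30, 35), [35, ∞)); the
3-level scheme merges the top two. Per-SD BMI standardization uses the
pooled within-dataset mean/SD. Stratified scans require both outcome
classes and ≥ 10 cases per stratum; failures yield missing records with
machine-readable reasons rather than estimates. PCs are computed per
dataset and never pooled across datasets — cohorts meet only at the
meta-analysis stage.

## Meta-analysis

Inverse-variance fixed effects: weights 1/se², pooled SE = sqrt(1/Σw),
two-sided normal p. Cochran's Q, chi-square(k−1) heterogeneity p, and
I² = max(0, (Q−(k−1))/Q)·100 floored at zero. When only an OR and 95% CI
are available, the SE is recovered as (ln hi − ln lo)/(2·1.959964); the
full-precision normal quantile is used rather than 1.96 so round-trips are
deterministic (the difference is below reporting precision). Worked
examples in the tests confirm that pooling per-study estimates read off at
2-decimal precision reproduces published-style combined ORs within ±0.02,
which is the propagation of the input rounding.

## Significance thresholds

The min-p permutation pairs each individual's case status with their PC1
value and shuffles the pairs together within each cohort, leaving local
ancestry, BMI, age and the remaining PCs fixed: this breaks
marker-outcome association while preserving the cohort's global
ancestry–outcome confounding structure, which is the quantity the
empirical null must carry. PCs are deliberately *not* recomputed inside
iterations — recomputation would undo the preserved linkage. Per
iteration the full interaction scan runs per cohort, per-marker estimates
are meta-analyzed, and the smallest p over testable markers is stored; the
threshold is the lower-α empirical quantile (linear interpolation; no
named convention is standard, so one is fixed and documented). Untestable
markers are excluded from the minimum. The desk-scale default is 1,000
iterations; production analyses use 10,000.

The effective-number-of-tests route computes eigenvalues of the
marker–marker Pearson correlation matrix (mean-imputed, constant markers
dropped) and takes the smallest k whose eigenvalue sum reaches 99.5% of
the trace; the threshold is α divided by the most conservative (largest)
count across datasets.

## Problem sizes in the shipped checks

The property-based checks run at desk scale chosen to give informative
Monte-Carlo error on one CPU: interaction-recovery coverage uses 100
cohorts of n = 1500 × 500 AIMs; null calibration uses 1000 independent
tests (cohorts of n = 800 with one marker per chromosome and a
homogeneous admixture proportion, so tests are genuinely independent);
the Šidák comparison uses 50 independent markers, n = 1200 individuals
(the scale of the study design this mirrors, and comfortably inside the
asymptotic regime the Wald null assumes) and 2000 permutations; decoding
accuracy uses 2000 markers × 300 individuals. The Beta spread of
individual admixture proportions is switched off in the two independence-
critical harnesses, since shared proportions correlate ancestry across
chromosomes.

## Known limitations

* The HMM assumes the simulator's own tract model; on real data,
  reference-panel misspecification and within-ancestry LD would lower
  accuracy relative to the figures here.
* Wald intervals are first-order; in very sparse strata the stratified
  ORs can be noticeably non-normal (the ≥ 10-case guard is a blunt
  protection).
* Fixed-effects meta-analysis only; heterogeneity is reported, not
  modelled.
* The permutation threshold applies to the genome-wide continuous
  interaction scan only, not to stratified or conditional follow-ups.
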