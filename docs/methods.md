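# Methods

This note records the models implemented in `morphoscore`, the assumptions
behind the synthetic-data generator, the defaults and why they were chosen,
and the numerical decisions that affect results. Nothing here reports an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design implemented

Two-stage endophenotype strategy. Stage 1 (training): a penalized logistic
discriminant is fit to case/control morphometry from a syndrome with a known
chromosomal lesion, yielding a single 0–1 neuroanatomical score. Stage 2
(application): the frozen weights are projected onto healthy imaging-genetics
cohorts — no refitting or recalibration — and the score becomes a
quantitative phenotype for (i) per-cohort candidate-region SNP association
pooled by fixed-effects IVW meta-analysis with a region Bonferroni
correction, (ii) fine-mapping of the pooled signal, (iii) QQ enrichment
against an ROI-based reference, and (iv) GREML SNP-heritability. Training
subjects never overlap the association cohorts, and cross-cohort scanner
differences are handled by analyzing cohorts separately and pooling
post hoc.

## Synthetic-data generator

The generator defines the standard study conditions; every downstream claim
in the test suite is a claim about data with this structure.

### Genotypes and LD

Haplotypes come from a latent-Gaussian threshold model: a Markov Gaussian
chain across SNP positions is thresholded at each SNP's allele-frequency
quantile and two haplotypes are summed into a dosage in [0, 2]. The implied
dosage correlation matrix is positive semi-definite by construction.

The candidate region defaults to **haplotype-block LD**: block lengths are
geometric (mean 6 SNPs), the latent step correlation within a block is
0.9999, and blocks are independent. Members of a block share their allele
frequency and are near-duplicates in dosage (r² ≈ 0.97), while across-block
r² ≈ 0 — the bimodal r² pattern of imputed candidate-region panels, where a
2 Mb region of ~110 well-imputed SNPs behaves like ~20 effectively
independent signals. Two facts drove this default over a graded AR(1)
decay. First, a dense imputed panel in a strong-LD region genuinely consists
of proxy clusters. Second, the binary threshold model has a √(1−r)
singularity (latent correlation 0.998 still yields dosage r² ≈ 0.8), so any
graded decay concentrates SNP pairs in an intermediate r² band (0.3–0.8)
that neither acts as a proxy nor decorrelates — a structure that is both
unrealistic for this kind of region and statistically adversarial for
localization. A distance-decay mode (`structure="distance"`, correlation
`ld_decay` at the mean marker spacing) and explicit `block_sizes` remain
available. The background panel uses independent SNPs.

MAF targets are uniform on [0.05, 0.5] at the block level; sample allele
frequencies recover the targets within binomial error.

### Morphometry

The feature vector follows the 3 measures × 2 hemispheres × 5124 vertices +
16 subcortical volumes = 30,760 layout. Descriptions of this kind of
feature set usually quote three measures and 5124 vertices without saying
whether the vertex count is per hemisphere; only the per-hemisphere reading
reproduces the 30,760 total, so the schema fixes that reading.

Feature noise is a **low-rank factor model**: 15 shared latent factors carry
90% of the per-feature variance, with factor scales spread geometrically
over a ratio of 300 (one dominant global-size-like mode down to fine
regional modes) plus an iid residual. This mirrors the empirical covariance
of vertex-wise data, where global and regional modes dominate and
registration leaves little independent per-vertex noise. The planted disease
axis is an equal-magnitude random-sign mixture of the factor directions:
disease-related reorganization moves the brain along modes of natural
anatomical covariation. This matters statistically: a 3-pooled-SD group
shift along an axis embedded in a ~15-dimensional covariance structure has a
Mahalanobis separation near 9 and is learnable from 38 subjects, whereas the
same shift along an arbitrary direction in 30,760-dimensional white noise is
provably not (the best achievable AUC is ~0.98 and estimation noise at n=38
reduces it far below that). Under an isotropic-noise reading, a perfect
leave-one-out AUC at this sample size would be unattainable for any
classifier; the factor model is the assumption under which the training
benchmark is meaningful.

Case/control training sets shift the case mean by `delta_case` (default 3)
pooled-SDs measured **along the axis**; the case group's ICV is reduced
proportionally (10% at the default shift), so the ICV-covariate logic is
exercised while `delta_case = 0` leaves the groups fully exchangeable.

### Cohorts, phenotype and confounding

The five cohorts default to sizes 184/653/325/250/451 (total 1863) with
distinct truncated-normal age ranges (an elderly cohort, three adult
cohorts, one pediatric cohort spanning 3–21 years, which is what the
age-16 stratified analyses exercise). The latent quantitative phenotype is

    s = β_causal · x_causal + polygenic(background) + covariates + ε,

scaled so the genetic share of the covariate-free variance equals `h2_true`
(default 0.8) and the single causal region SNP explains `causal_var_frac`
(default 1%) of it. Features are `baseline + s · w_true + noise` plus an
additive per-cohort scanner offset (SD 0.3 per feature), which is what makes
per-cohort analysis + meta-analysis necessary rather than cosmetic.
Covariate effects default to −0.2 SD per SD of age, +0.1 for sex and +0.05
per SD of PC1.

All randomness flows from one integer seed through named CRC32-keyed
substreams (`_rng.substream`), so each stage can be regenerated
independently and datasets are bit-reproducible.

## Score model

Objective: mean logistic negative log-likelihood plus
λ[α‖w‖₁ + (1−α)/2‖w‖₂²] on the morphometry weights only; the intercept and
the standardized ICV coefficient are never penalized. Defaults α = 0.5, 30
log-spaced λ values from the glmnet-style λ_max down to λ_max/100.
Standardization uses training rows only and is refit inside every
cross-validation fold; zero-variance features keep weight 0.

Optimizer: monotone FISTA (proximal gradient with Nesterov momentum, restart
on overshoot, and a plain-gradient confirmation step before declaring
convergence), step 1/L with L from power iteration, L1 handled by soft
thresholding and the L2 term folded into the smooth part. Tolerance 1e-8 on
the relative objective change, max 10,000 iterations. Along the λ path the
penalized columns are screened with the sequential strong rule and every
solution is verified against the full KKT conditions (violators re-enter),
so path solutions are exact while full-gradient passes are needed only a few
times per λ. λ is chosen by leave-one-out CV AUC (Mann–Whitney with ties at
½), breaking ties toward the larger λ.

Projection applies the trained standardization and the trained ICV
coefficient to new subjects — the score must be computable per subject, so
ICV enters at projection exactly as at training. Scores are sigmoid outputs,
strictly inside (0, 1). Note that when the training separation is strong the
projected cohort distribution is pushed toward the sigmoid tails, which
attenuates the linear information in the score; the pipeline's heritability
estimate of the *projected* score is therefore biased below the latent
`h2_true` by roughly the squared correlation between projected and latent
scores. This is a property of the design being modeled, not of the
estimator (REML recovery tests on unsquashed phenotypes are unbiased).

## Association and meta-analysis

The score is the regression outcome and the dosage the predictor (the
reported per-allele effects live on the 0–1 score scale), adjusting for age,
age², sex and seven ancestry PCs. `scan_region` projects the covariates out
of the score and all dosage columns once (Frisch–Waugh–Lovell) and is
algebraically identical to per-SNP OLS; p-values use the t distribution
with n − k − 2 degrees of freedom. SNPs monomorphic within a cohort are
flagged and excluded from pooling rather than raised as errors. ICV is not
an association covariate.

IVW pooling is fixed-effects only (wᵢ = 1/seᵢ²); Cochran's Q and
I² = max(0, (Q−(k−1))/Q)·100 are reported as diagnostics, never used to
switch models. Alleles are harmonized by sign flip before pooling. The
Bonferroni correction treats the 110 tests as independent — deliberately
conservative given the block LD.

## Fine-mapping

For each configuration c with |c| ≤ K: likelihood MVN(z; 0, Σ + σ²Σ
diag(c) Σ), prior γ^|c|(1−γ)^(m−|c|), null included; posterior normalized
over the enumeration. Defaults K = 2, γ = 0.01, σ (non-centrality scale)
= 5.2, ρ = 0.95, enumeration capped at 200,000 configurations. Likelihood
ratios against the null are computed with the matrix-determinant lemma and
the Woodbury identity, so each configuration touches only its |c| × |c| LD
block; exhaustive enumeration of all pairs in a 110-SNP region takes
seconds, and tests verify exact agreement (1e-10) with full-covariance MVN
densities. Σ is ridged by ε = max(0, 1e-6 − λ_min) when near-singular
(near-duplicate proxies make this the normal case) and ε is recorded in the
output. The ρ-credible set takes SNPs in decreasing PIP order (ties to the
smaller genomic position) until their cumulative share of total PIP mass
reaches ρ; with uniform PIPs this reduces to ⌈ρm⌉ SNPs, and under block LD
it typically returns the causal block.

## Heritability

GRM: the standard frequency-standardized estimator over SNPs passing the
MAF filter (default 0.01), missing dosages mean-imputed per SNP; written and
read in the GCTA text format (`.grm.gz` triplets + `.grm.id`). In the
pipeline the GRM combines the candidate region with the simulated polygenic
background panel, since a genome-wide panel is not part of the design.

REML: the model y = Xβ + g + ε, V = σ²g A + σ²e I is fit in the eigenbasis
of A — one symmetric eigendecomposition, after which every likelihood,
score and average-information evaluation is O(nk). Updates are AI steps
with step-halving along the AI direction when the full step overshoots, and
an EM step as the final fallback; components are clamped at a small
positive floor; the restricted likelihood never decreases across accepted
iterations; convergence at |Δℓ| < 1e-6. h² = σ²g/(σ²g+σ²e) with a
delta-method SE from the inverse AI matrix. The test of σ²g = 0 uses the
boundary mixture ½χ²₀ + ½χ²₁ on the restricted LRT; the null model's REML
is closed-form (OLS residual variance). The mixture test is known to be
mildly anti-conservative when the GRM carries little relatedness contrast
(few markers relative to subjects); the null-calibration test documents the
observed rate at its stated size. The restricted likelihood is reported in
the convention that includes log|X'V⁻¹X|, so reparameterizing X shifts it
by a constant log-determinant while all estimates and LRTs are invariant.

## Enrichment

Expected null quantiles use −log₁₀(i/(n+1)); pointwise envelopes come from
Beta(i, n−i+1) quantiles at α/2 and 1−α/2. When the two p-value sets differ
in size the reference quantile function is interpolated at the (i−½)/n
grid. The tail-shift statistic is the mean difference of the top decile of
paired −log₁₀ quantiles. The enrichment flag compares the *mean* of the top
decile of observed quantiles with the mean of the envelope's upper bound at
those ranks: an "any point outside" rule violates the nominal flag rate
under the null (multiplicity across correlated order statistics), and an
"all points outside" rule fails whenever the signal sits in a single LD
cluster; the mean rule holds the null rate near α and detects a planted 1%
causal signal reliably, both of which the tests measure. The reference arm
in the pipeline is simulated: the same genotypes tested against a noisy
single-volume phenotype, standing in for ROI-based summary statistics.

## Pipeline

One `RunConfig` drives simulate → train → project → scan → meta (+
leave-one-cohort-out at the top SNP) → fine-map → enrichment → heritability.
The training set is always a separate simulated case/control cohort sharing
the planted axis and factor structure with the association cohorts
(matching the train-then-apply design), produced from a shifted seed so
subjects never overlap. Stage failures are recorded in the report and do
not abort independent downstream stages. Reruns with the same config and
seed are bit-identical; the report carries a config hash. The CLI
(`morphoscore run-all | stratified | simulate`) is a thin wrapper over
these functions.

## Problem sizes used in the test suite

Analytic and oracle checks run at the sizes stated in their tests (n = 38
training sets at the full 30,760 features; oracle instances at n ≤ 60).
Simulation-based checks use: h² recovery, 20 replicates per level at
n = 1000 / M = 2000; scan localization, 200 replicates at n = 1863 with a
minimal feature schema (the scan consumes the latent score, so feature
dimension is irrelevant there); fine-mapping recovery, 100 replicates at
m = 110 under the ρ = 0.5 AR(1) LD specified for that benchmark; null
calibration, 2000 association replicates and 1000 envelope replicates; the
end-to-end pipeline power property, 5 replicates at n = 1863 with a reduced
feature schema. These sizes are the package's chosen balance between
Monte-Carlo resolution and a test suite that runs in minutes; each test
states its own size and threshold.

## Known limitations

- The generator emulates the statistical structure of morphometry and
  imputed genotypes, not images: no surfaces, no registration error, no
  imputation-quality (INFO) variation, no missing data in features.
- The factor-model noise and in-span disease axis are assumptions; under
  heavy-tailed or isotropic feature noise the training benchmark would
  degrade as described above. Passing tests certify behavior under the
  stated generative model, not on any real cohort.
- LD is either block-structured or Markov by distance; long-range LD and
  population-specific patterns are out of scope, as are X-chromosome
  handling, mixed-model association, random-effects meta-analysis and
  functional fine-mapping priors.
- The projected score's sigmoid saturation attenuates downstream effect
  sizes when training separation is extreme; in the real design the
  training population is far from the application population, which keeps
  projected scores mid-range.
- REML assumes Gaussian residuals and a single genetic variance component;
  the heritability reported for the projected score inherits the
  attenuation noted above.
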