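# Methods

## Design

The package implements a two-sample Mendelian randomization (MR) analysis
of a continuous exposure (circulating 25OHD on a standardized log scale)
on a binary outcome (self-reported fatigue, "tired or low energy nearly
every day over the past two weeks"), using independent SNPs as
instrumental variables. SNP–exposure associations come from one study,
SNP–outcome associations from a second, non-overlapping study; the MR
assumptions are the usual three (relevance, independence from confounders,
exclusion restriction), with the sensitivity modules probing the last two.

## Harmonization and orientation

Instruments are the rsid intersection of the two studies. A SNP is
retained only when both studies report the same unordered allele pair; the
outcome effect is sign-flipped when its effect allele is the exposure's
other allele. Every instrument is then re-oriented so the effect allele is
the **exposure-decreasing** allele, and `beta_exposure` is stored as the
positive SD-decrease per allele copy. Consequences:

- all MR slopes are log-odds per 1-SD *decrease* in exposure, matching the
  direction in which results are reported;
- the MR-Egger requirement that all exposure betas share one sign holds by
  construction.

Palindromic SNPs (A/T, C/G) carry no strand information in their labels.
Default policy `infer_by_eaf` orients them by comparing effect-allele
frequencies between studies and refuses a call when either frequency is
within 0.08 of 0.5 (dropping the SNP); policy `drop` removes them
outright. The window 0.08 is conventional for biobank-scale European-
ancestry panels; none of the seven 25OHD instruments is palindromic, so
the policy only matters for general use.

An externally sourced instrument (in the motivating analysis, the
low-frequency CYP2R1 variant whose effect estimate comes from a different
GWAS) is mapped onto the reference scale by a **through-origin**
least-squares regression of reference-scale betas on source-scale betas
over shared SNPs; the target beta and SE are both multiplied by the slope.
Through-origin is chosen (the regression direction and intercept treatment
were genuinely open) because both scales measure the same standardized
quantity and must agree at zero; the scaling preserves each SNP's z-score.

## Estimators

Per-SNP Wald ratio `beta_outcome/beta_exposure` with first-order
delta-method SE `se_outcome/|beta_exposure|` (exposure-side noise
neglected; checked by simulation to be within 5% of the true ratio SD at
instrument CV < 0.1). IVW pools ratios with weights
`w_j = beta_exposure_j^2 / se_outcome_j^2`; the fixed-effect SE is
`(sum w)^(-1/2)`, and the multiplicative-random-effects variant multiplies
it by the residual SD of the weighted through-origin regression, floored
at 1 (the two coincide when Q <= df, as in the motivating analysis).
MR-Egger adds an intercept to that weighted regression; its SEs use the
same max(1, sigma) floor, with a normal reference by default and a t(k−2)
option (which reference the original software used is not stated
anywhere, so both are provided). The weighted median interpolates the
weighted empirical CDF of ratios at 0.5 (plain, non-penalized weights) and
takes its SE from a parametric bootstrap — betas resampled from
Normal(observed, se) on both sides, default 5000 draws, seed mandatory.
Cochran's Q uses the IVW weights about a reference slope; I² is the
excess-over-df share of Q and τ² the DerSimonian–Laird moment estimator.
All p-values are two-sided and CIs 95%.

## Power and meta-analysis

Binary-outcome MR power uses the analytic non-centrality approximation:
`b = K(OR/(1+K(OR−1))−1)`, `v = (K(1−K)−b²)/(N·r²)`, power =
P(χ²₁(b²/v) > χ²₁ critical). At the fatigue-study design values
(N = 327,478, K = 0.0596, r² = 0.05, α = 0.05) this gives 85% power for
OR 1.10 and 86% for OR 0.90. The meta-analysis module pools standardized
mean differences by DerSimonian–Laird, recovering SEs from printed 95% CIs
with z = 1.96; the fixed-effect result is retained alongside. Fed the
three published vitamin-D supplementation trials it returns pooled SMD
−0.29 (95% CI −0.83 to 0.24), I² = 77.2%, p_het = 0.012. Note the source
report prints the pooled value as "0.29" with a CI that cannot contain
+0.29; the sign implied by the inputs is negative, and this package
reports that value. I² from the printed (2-dp rounded) inputs is 77.2
versus the published 77.3; propagating the input rounding spans roughly
76.1–78.3, so the two are consistent at input precision.

## Synthetic cohorts

`simulate_cohorts` draws two fully disjoint cohorts (default 20,000
exposure / 50,000 outcome) sharing one genetic architecture: `n_snps = 7`
independent biallelic SNPs, maf ~ U(0.05, 0.45), dosages Binomial(2, maf)
(Hardy–Weinberg), per-SNP effects with lognormal(0, 1.0) magnitude spread
and random sign, jointly scaled to explain `target_r2 = 0.05` of exposure
variance. The wide effect-size spread mirrors the real instrument panel
(one dominant common signal several-fold larger than the rest plus a
low-frequency larger-effect variant); it matters because a panel of
near-equal instrument strengths leaves the Egger intercept essentially
unidentified. The exposure is built with unit total variance analytically
(genetics + optional confounder loading + Gaussian noise), so "mean 0, SD
1" holds without empirical re-standardization and the generating betas
remain exact.

The outcome cohort's ordinal 4-level report follows a cumulative-logit
construction: linear predictor `eta = −theta·X_latent + sum_j delta_j·
g̃_j + c_y·U`, where `X_latent` is that cohort's own (unobserved) exposure
analogue, `g̃_j` is the dosage of the exposure-*decreasing* allele, and
the three intercepts are solved by root-finding so the marginal category
frequencies match the configured targets (defaults 47.31 / 40.98 / 5.75 /
5.96%, top-category prevalence 5.96%). Dichotomizing at the top category
therefore yields an exact logistic model. Pleiotropic effects `delta_j ~
Normal(pleiotropy_mean, pleiotropy_sd)` act on the decreasing-allele
dosage so that a nonzero mean is *directional on the harmonized
orientation* — applying them on an arbitrary allele orientation would let
harmonization's sign flips cancel them on average, making "directional"
pleiotropy undetectable in principle. InSIDE holds because deltas are
drawn independently of instrument strength.

What the generator does **not** emulate: LD between instruments, sample
overlap, imputation dosage uncertainty, population stratification (the
emitted sex/centre/PC covariates are pure nuisance by default), assortative
mating, and selection into the cohorts. Passing tests therefore certify
the statistical machinery under clean two-sample assumptions, not
robustness to those real-data complications.

Summary statistics are produced from the cohorts by per-SNP OLS
(continuous traits; closed form, optional Frisch–Waugh covariate
residualization) and per-SNP Newton–Raphson logistic regression
(gradient max-norm < 1e-8, at most 25 iterations; fits with diverging
log-odds (> 15 in magnitude) are flagged as separation and the SNP
skipped; monomorphic SNPs are likewise skipped).

## Numerical and operating characteristics

Established by the acceptance suite at desk scale (20k/50k cohorts,
seven SNPs, r² = 0.05, prevalence 5.96%):

- IVW, Egger and Q agree with independent normal-equation arithmetic to
  1e-10;
- IVW 95% CI coverage of theta ∈ {0, 0.1, 0.3} over 500 seeded replicates
  per value lies within [0.92, 0.98] (non-collapsibility of the odds
  ratio attenuates the marginal SNP–outcome betas by well under 2% at
  these effect sizes, negligible against the sampling SE);
- with directional pleiotropy delta = 0.02 the Egger-intercept rejection
  rate at alpha = 0.05 exceeds the null rate by at least 3x (1000
  replicates per arm), and the intercept estimate is centred on 0.02;
- harmonization recovers a known instrument set exactly under all 2³
  allele-label/orientation scrambles per SNP.

The replicate counts and cohort sizes above are the package's chosen
simulation scale; the full suite runs in a few minutes on one CPU.

## Pipeline conventions

`run_analysis` computes the estimate table for every configured outcome
threshold (the four ordinal dichotomizations and/or a continuous variant
that codes the categories 0–3 and uses per-SNP OLS — the coding is a
package choice, stated here because the source analysis does not specify
one), while diagnostics (Q, Egger intercept, leave-one-out, single-SNP,
scatter table) refer to the first threshold. The scatter "plot" is emitted
as a data table; no plotting layer is bundled. One master seed drives the
simulation and all bootstraps; re-running a config reproduces
byte-identical tables (floats serialized at 10 significant digits). The
source report itself states 307,952 below-threshold individuals in one
place and 307,946 in another; the pipeline simply reports whatever its
input yields.

## Known limitations

First-order Wald SEs understate uncertainty for weak instruments (CV >
0.1); no MR-PRESSO/mode-based/multivariable estimators; no LD-aware MR;
no Steiger filtering; the PRS confounder check is a per-covariate F-test
without multiplicity control; the power formula is the standard analytic
approximation and ignores instrument-estimation noise.
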