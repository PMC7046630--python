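# Methods

This note records the statistical models, the synthetic data generator,
and the numerical choices behind `mlmwas`. It states what the code
computes; quantitative behavior is established by the test suite and the
acceptance report (`scripts/acceptance.py`), not by claims made here.

## Data model and preprocessing

Methylation enters as an n × m matrix of beta values in [0, 1] (n
individuals, m probes) with per-probe genomic annotation (chromosome,
position, gene, orientation). Quality control removes probes whose beta
standard deviation falls below 0.02 (near-invariant probes carry no
usable signal and destabilize standardization). Probes are then
standardized to mean 0, variance 1 using the population (divisor-n)
standard deviation, so the omics relationship matrix defined below has
average diagonal exactly 1.

Optional covariate residualization regresses each standardized probe on
an intercept plus fixed covariates (continuous columns as-is,
categorical columns as drop-first dummies) and restandardizes the
residuals. Exactly collinear designs are rejected with the offending
column named.

## Omics relationship matrix (ORM)

For standardized probes W (n × m), the ORM is `A = W W′ / m` — the
methylation analogue of a genomic relationship matrix: positive
semi-definite, average diagonal 1. Principal components used as scan
covariates are eigenvectors of A scaled by the square root of their
eigenvalues, each signed so the largest-magnitude loading is positive.

Window exclusion removes, for a target probe, the probe itself plus all
probes on the same chromosome within half the window width (inclusive)
of its position; the default window is 100 kb. Excluding k probes from
an m-probe ORM uses the exact downdate `A_new = (m A − E E′) / (m − k)`
where E holds the excluded columns, avoiding a rebuild per probe.

## OREML variance components

The variance model is `y = Cβ + Σ_k g_k + e` with
`var(y) = Σ_k A_k σ_k² + I σ_e²`. The headline quantity is
`ρ² = σ_o² / (σ_o² + σ_e²)` with `σ_o² = Σ_k σ_k²`, the fraction of
phenotypic variance captured by genome-wide methylation. For 0/1
case-control phenotypes ρ² is reported on the observed scale only; no
liability transformation is offered because methylation associations mix
causes and consequences of disease, making the liability mapping's
assumptions inappropriate. For a balanced-ish binary trait the total
`σ_P² = σ_o² + σ_e²` should track the binomial variance P(1 − P) of the
case fraction, which the tests check.

Two fitting paths:

- **Single component.** After one eigendecomposition `A = U D U′` the
  covariance is diagonal in the rotated basis. The residual scale is
  profiled out analytically, leaving a one-dimensional restricted
  likelihood in log(σ_o²/σ_e²) maximized by bounded scalar search. This
  is exact in the scale, cheap (O(np²) per evaluation), and robust when
  the optimum sits on the σ_o² = 0 boundary, where Newton-type
  iterations stall.
- **Multiple components** (and `method="generic"`). Average-information
  REML: an EM first step, then AI steps with step-halving toward the
  current iterate whenever a step would decrease the restricted
  likelihood, a damped-EM fallback, variance floors at 1e-6 · var(y),
  and convergence at |Δ log-lik| < 1e-8 within 100 iterations.

The two paths are genuinely different algorithms and are checked against
each other in the tests. Standard errors of ρ² come from the inverse
average-information matrix by the delta method. Fixed effects (including
cell-type proportions, with one compositional reference category
dropped) are GLS estimates at the fitted covariance.

## Association engines

All engines report effect b, standard error, and p per probe, plus the
genomic inflation factor λ = median(χ²)/0.4549 (the null median of a
1-df chi-square).

- **linear** — per-probe OLS with optional fixed covariates; two-sided t
  test with n − p − 2 degrees of freedom.
- **linear_pc** — the same scan with the top ORM principal components
  appended as covariates.
- **moa** — mixed-linear-model association, two-step (EMMAX-style):
  variance components are estimated once under the genome-wide null
  model, then each probe is tested by GLS against the fitted covariance,
  `b_i = w_i′V̂⁻¹ỹ / (w_i′V̂⁻¹w_i)`, `se_i = (w_i′V̂⁻¹w_i)^{-1/2}`,
  with ỹ the covariate-adjusted phenotype; χ²(1 df) p-values. All probes
  are rotated into the eigenbasis of A once, so the scan is one matrix
  product.
- **moment** — multi-component scan excluding the target. An initial
  linear scan splits probes into a most-associated group (p below a
  grouping threshold, default 0.05) and the rest; each group becomes its
  own random component. For every tested probe, all probes within the
  exclusion window are removed from *both* components by ORM downdating,
  and the probe is tested as a fixed effect by joint GLS. Variance
  components are estimated once on the full groups and reused
  (refit-per-probe is available but costs a REML fit per probe). If no
  probe passes the grouping threshold the engine falls back to a single
  genome-wide component and records that in the output notes.

The grouping threshold default of 0.05 (rather than a Bonferroni-style
cut) is deliberate: the associated group must be large enough to absorb
probes driven by shared confounders (cell composition, batch) into their
own variance component; with a near-empty group the engine degenerates
toward a single-component model that can be anti-conservative under
confounding. This choice is checked by the confounding-control suite.

## Scoring and classification

- **BLUP weights.** Joint shrinkage estimates of all probe effects,
  `û = σ̂_u² W′V̂⁻¹(y − Cβ̂)` with `σ̂_u² = σ̂_o²/m`, computed in the
  eigenbasis; equivalent to ridge regression with penalty σ̂_e²/σ̂_u²
  (tested).
- **Thresholded weights.** Per-probe MWAS effects restricted to probes
  below each p-value cutoff in a grid.
- **MPS.** A target individual's methylation profile score is the
  weighted sum of their target-standardized probe values over the probes
  shared with the weight table; the matched/missing probe counts are
  reported.
- **CTP score.** The analogous weighted sum of estimated cell-type
  proportions using OREML fixed effects.
- **Combined score.** Score components are combined by a least-squares
  regression of discovery status on the discovery-side components
  (standardized by their discovery mean/SD) — for a 0/1 outcome this is
  the Fisher discriminant direction, and unlike a logistic fit it stays
  defined when an in-sample component separates the classes perfectly.
  The fitted coefficients are applied to the target components mapped
  through the same discovery statistics. An unweighted sum would let a
  weak component dilute a strong one; fitting the weights in the
  discovery cohort keeps the target evaluation out-of-sample.
- **Classification.** Mann-Whitney (midrank) AUC with a DeLong 95%
  confidence interval; logistic regression of status on the
  standardized score for an odds ratio per score SD. The AUC estimator
  is checked against the binormal closed form Φ(d/√2).

## Cell-type deconvolution

Reference-based: each individual's beta vector over signature probes is
fit by constrained least squares `min ‖x − R′π‖²` subject to π ≥ 0 and
Σπ ≤ 1 (SLSQP, warm-started from clipped OLS). The inequality (rather
than equality) sum constraint means estimated proportions sum to
slightly less than 1 under noise; downstream compositional handling
drops one reference cell type where an exact-sum table would be
collinear with an intercept.

## Cross-cohort agreement and power

- **r_b** — correlation of probe effects across two estimate sets,
  correcting each variance for estimation error:
  `r_b = cov(b₁,b₂) / √((var(b₁) − mean(se₁²))(var(b₂) − mean(se₂²)))`,
  clipped to [−1, 1] (flagged) with a delete-one jackknife standard
  error over probes. When the error-corrected variance is non-positive
  the estimate is undefined and an error is raised rather than a number
  returned.
- **Stepwise CTP logistic** — backward elimination from the full model
  (proportions in percent), dropping the largest-p term until all
  remaining have p < 0.05; odds ratios per percentage point with Wald
  CIs and a Bonferroni flag across the initial K tests.
- **Replication sample size** — normal-approximation balanced two-group
  n for a standardized difference d: per-group `2(z_{1−α/2} + z_power)²/d²`
  (z_{1−α} one-sided), total twice the per-group ceiling. Sidedness is
  an explicit argument because reported power calculations rarely state
  it.

## Synthetic data generator

Cohorts are generated on the logit scale and squashed back to beta
values:

1. A purified-cell reference (K cell types × m probes) with ~m/3 strong
   signature probes; full signature rank is checked.
2. Per-individual cell proportions from a Dirichlet (concentration 60)
   around neutrophil-dominant means; cases get a mean composition shift
   (default +0.03 neutrophils, balanced by the other types) — this makes
   cell composition a genuine confounder of case status.
3. Mixture betas `π·R` → logit; covariate footprints (age, smoking, sex)
   on random probe subsets; per-batch probe offsets; residual noise;
   a fraction of probes flattened to near-invariance (QC fodder).
4. Causal probes: a case-control shift of `effect_sd` standard
   deviations of the probe's logit-scale values, random sign. With a
   target ρ², effect sizes are solved from
   `ρ² = P(1−P)·D² / (1 + P(1−P)·D²)` with D² the summed squared
   standardized effects and P the case fraction.
5. Probe positions are spread over 22 autosomes at 20–40 kb spacing, so
   100 kb windows cover neighbours.

Cohort pairs share the cell reference and the full probe layout
(low-variance set, causal probes, effect sizes, annotation) while
drawing individuals independently; the target cohort keeps a random
subset of the discovery probes (`probe_overlap`) to emulate platform and
QC differences. All randomness flows from one seed through named
`SeedSequence` streams, so outputs are reproducible and adding draws to
one stream does not perturb the others.

### Generator scope and limitations

The generator is a test harness, not a biological model: no CpG
correlation structure beyond what the shared cell-composition mixture
induces, no genomic autocorrelation along chromosomes, logit-normal
rather than empirically calibrated beta distributions, and covariate
footprints with arbitrary (if plausible) magnitudes. Effect sizes are
injected as mean shifts in cases only, which is adequate for testing
detection, calibration and transfer but does not model dose-response or
reverse causation. Conclusions supported by this package are about the
statistical machinery, not about any real methylome.
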