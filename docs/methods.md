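# Methods

## The problem

`mrmediation` implements a summary-statistics Mendelian randomization (MR)
workflow for interrogating *mediation*: given a modifiable exposure X, a
candidate mediator Z and a disease outcome Y, how much of the causal effect
of X on Y flows through Z?  The motivating use case is screening many
candidate mediators of a protective exposure on a common binary outcome
(roughly half the study sample being cases), with all traits observed only
as GWAS summary statistics.

The decomposition rests on three MR layers:

1. **Univariable two-sample MR** for the *total* effect of X on Y: per-SNP
   Wald ratios `by_j/bx_j` pooled by the inverse-variance weighted (IVW)
   estimator, which is the zero-intercept weighted regression of outcome
   betas on exposure betas with weights `1/se_y^2`.
2. **Two-step MR**: step 1 estimates X → Z (the mediator regressed on the
   exposure's instruments), step 2 estimates Z → Y.
3. **Multivariable MR (MVMR)** with X and Z as joint exposures, giving each
   trait's *direct* effect on Y conditional on the other.

Mediation then combines these:

* **Product method** (headline): `indirect = beta_step1 * beta_Z_direct`,
  with the first-order delta-method SE
  `sqrt(b2^2 se1^2 + b1^2 se2^2)` (a cross term `se1^2 se2^2` is available
  behind a flag).
* **Difference method**: `indirect = total - beta_X_direct`, SE combined in
  quadrature with the covariance between the two fits ignored; the output
  is flagged conservative.
* **Proportion mediated** `indirect/total`, with a delta-method CI on the
  ratio; when the indirect and total effects point in opposite directions
  the value is flagged as not a proportion.

All outcome-side arithmetic stays on the log-odds scale; odds ratios appear
only at the reporting boundary.  For a *common* binary outcome the odds
ratio is non-collapsible, so the product and difference decompositions
estimate genuinely different quantities and disagree systematically, the
difference method being conservative; the package reproduces this in
simulation (see below).

## Estimators and numerical conventions

* **Wald ratio** SE is first order (`se_y/|bx|`); exposure-side
  uncertainty is ignored, the standard two-sample convention.
* **IVW** defaults to *multiplicative random effects* for ≥ 2 SNPs: the
  fixed-effect SE is inflated by `sqrt(max(1, Q/(n-1)))` where Q is
  Cochran's heterogeneity statistic.  A fixed-effects model is available by
  flag.  A single SNP falls back to the Wald ratio exactly.
* **MR-Egger** orients every SNP so `bx >= 0` before fitting the weighted
  regression with a free intercept; slope and intercept SEs use the same
  multiplicative inflation with `n-2` degrees of freedom.  An intercept of
  magnitude ≥ 0.002, or with p < 0.05, flags directional pleiotropy
  (both thresholds configurable).
* **Weighted median**: per-SNP ratios sorted, cumulative weight midpoints
  `p_j = sum_{i<=j} w_i - w_j/2`, linear interpolation at 0.5; the SE comes
  from a seeded parametric bootstrap of `(bx, by)` from their SEs
  (default 1000 draws).
* **MVMR-IVW**: zero-intercept WLS of `by` on the K-column exposure-beta
  matrix, weights `1/se_y^2`; SEs from the unscaled weighted-regression
  covariance times `sqrt(max(1, Q_A/(n-K)))`.
* **Q_A** uses weights
  `1/(se_y^2 + sum_k b_k^2 se_xk^2 + 2 sum_{k<l} b_k b_l rho_kl se_xk se_xl)`;
  the phenotypic correlation `rho` enters only when both exposures were
  measured in one cohort, and is otherwise zero.  The correlation matrix is
  estimated as the Pearson correlation of per-SNP z-scores over shared SNPs
  that look null in both traits (|z| < 2), projected to the PSD cone if
  pairwise estimation leaves tiny negative eigenvalues.
* **Conditional F** for exposure k minimises the Q_A-form objective with
  trait k in the outcome role (Nelder–Mead from a WLS start, tolerance
  scaled by the objective), and divides by `n - K + 1`; K = 1 reports
  `mean(bx^2/se_x^2)`.  F > 10 is the conventional adequacy rule.  When
  fixture SEs are exactly zero the residual variance is floored at 1e-12,
  so "infinitely strong" instruments yield a huge finite F rather than a
  division error.
* **Q-het** minimises Q_A over the effect vector from the IVW start;
  SEs by seeded nonparametric bootstrap over SNPs (default 500).  Note
  that Q-het's effect-dependent weights absorb part of the
  regression-dilution bias that IVW carries, so the two estimators agree
  only in the strong-instrument limit.
* Two-sided p-values use the normal distribution throughout (not t), and
  95% CIs use the 0.975 normal quantile — the summary-data MR convention.

## Harmonisation

Instruments are selected at p < 5e-8 and greedily clumped at r² < 0.001
(SNPs visited in ascending p; unknown LD counts as independence, matching a
post-clumping analysis state).  Outcome records are aligned to the
exposure's effect allele: matching alleles pass, swapped alleles negate the
beta and complement the frequency, and palindromic (A/T, C/G) variants are
resolved by frequency — dropped when either frequency is missing or within
0.08 of 0.5, sign-flipped when the two frequencies disagree in side of 0.5.
The window is a conservative standard choice.  Proxy substitution for SNPs
missing from the outcome would require a reference panel and is out of
scope; such SNPs are dropped with a recorded reason.  MVMR uses the union
of per-exposure instruments, de-duplicated, clumped across the union, and
aligned to the outcome's allele frame.

## The synthetic-data generator

The generator exists so that every stage of the workflow can be exercised,
and its statistical claims tested, without any data download.  The
structural model (module docstring of `mrmediation.simulate`) has unlinked
biallelic SNPs in three blocks — exposure instruments, mediator
instruments, and an optional pleiotropic block whose SNPs affect both the
exposure and the outcome directly — plus one standard-normal confounder
with loadings on all three traits.  Per-SNP instrument effects are drawn
`N(0, h2/m)` on the standardised-genotype scale (heterogeneous, as in real
GWAS); directional pleiotropy is oriented to the exposure-raising allele
(otherwise random allele labelling would cancel it).  X and Z are
standardised to unit variance before entering the outcome model, so all
effects are per SD.  Quantitative traits pass through a rank-based
inverse-normal transform (Blom offset 3/8) before their GWAS, mirroring
biobank pipelines; per-SNP statistics come from simple linear regression or
univariate logistic regression (vectorised Newton–Raphson, float32
iterations with a float64 polish, verified against statsmodels to 1e-8).

Defaults (the package's study conditions, chosen once):

| parameter | default | rationale |
|---|---|---|
| n per cohort | 20,000 | desk-scale replicates, seconds each |
| m (exposure / mediator SNPs) | 150 / 100 | a few hundred genome-wide hits |
| h² (exposure / mediator) | 0.35 / 0.30 | mean per-SNP chi² ≈ 47 / 60, i.e. instruments comfortably past 5e-8 as in large biobank GWAS |
| theta (X→Z) | −0.24 | an inverse hormone-like response |
| tau (Z→Y) | ln(1.08) | a modest adverse mediator effect |
| delta (X→Y direct) | ln(0.66) − theta·tau | total effect ln(0.66), protective |
| confounder loadings | 0.25 each | moderate shared confounding |
| case fraction | 0.537 | a common outcome |
| MAF | U(0.05, 0.5) | common variants |

The baseline log-odds `b0` is calibrated by bisection on a 200k-individual
pilot draw (tolerance well inside ±0.02 on the case fraction).  The same
pilot yields the **true total effect** for a binary outcome as the marginal
do-intervention contrast `logit E[Y | do(X+1)] − logit E[Y | do(X)]`
(shifting X by one SD shifts the linear predictor by `delta + tau*theta`);
an observational fit would absorb confounding and is not the causal
estimand.  For the continuous-outcome variant the total is exactly
`delta + theta*tau` and the indirect exactly `theta*tau` (the collapsible
case).

Sample designs: `disjoint` (independent cohorts per trait), `overlap(f)`
(exposure and mediator GWAS share a fraction f of individuals; f = 1 is a
fully shared biobank), and `split` (one cohort halved: discovery and
exposure betas from half A, mediator/outcome betas from half B).  Output is
deterministic: a (config, seed) pair regenerates byte-identical files.

`simulate_study_fast` is an economy replicate generator for the repeated
experiments: identical generative model, but disjoint cohorts share the
population MAFs, and the expensive per-SNP logistic outcome GWAS is
computed only at SNPs that can enter downstream MR (those passing
selection for the exposure or mediator).

### What the generator does and does not emulate

It reproduces the statistical structure the estimators consume: per-SNP
linear/logistic betas and SEs with realistic noise, winner's curse under
shared-sample selection, confounding, horizontal pleiotropy, sample
overlap, and non-collapsibility of the odds ratio.  It does **not**
simulate LD blocks (clumping is exercised via synthetic r² maps),
population structure, relatedness, measurement error in the exposure
questionnaire sense, or X-chromosome dosage.  Passing tests therefore
certify the estimators and workflow logic under the stated model — not
robustness to the full messiness of real cohort data.

## Replicated experiments and the sizes used

* **Null calibration** — 1000 replicates of the global null (n = 20,000,
  m = 150, disjoint cohorts, binary outcome): the IVW two-sided test at
  nominal 5% rejects in 3–7%.
* **Recovery** — 500 continuous-outcome replicates of the default
  scenario: the mean product-method indirect estimate lands within 3
  Monte-Carlo SEs of theta·tau.
* **Coverage** — 500 binary-outcome replicates, half default scenario and
  half null: the IVW 95% CI covers the true total effect 92–97% of the
  time.  The binary outcome matters here: with a continuous outcome at
  this n the outcome-side SEs are tiny and the ~3% attenuation from
  winner's curse plus regression dilution (inherent to selecting
  instruments from the exposure GWAS itself) becomes visible against the
  CI width; in the case-control noise regime the method actually operates
  in, it is negligible.
* **Winner's curse** — 200 paired replicates with a deliberately modest
  heritability (h² = 0.2) so the 5e-8 threshold is binding: the mean
  signed excess of estimated over generative per-allele effects across
  selected SNPs is positive when selection and estimation share the full
  cohort, and shrinks to zero when instruments discovered in half A are
  re-estimated in half B (the half that feeds the downstream GWAS).
* **Method disagreement** — 200 binary-outcome replicates of a
  strong-mediation scenario (theta = 0.5, tau = 0.7, delta = −0.5, 53.7%
  cases): the difference method is systematically conservative relative to
  the product method.  Under the default (paper-scale) effect sizes the
  non-collapsibility gap is of order 1e-4 and unresolvable at feasible
  replicate counts, so the property is demonstrated where it is
  measurable.

Replicate counts and cohort sizes above are the package's chosen problem
sizes; each experiment accepts `n_reps`/`seed` arguments.

## Prioritisation workflow

Mediators are screened in stages.  *Evidence* means the 95% CI excludes
the null; *consistency* means the weighted median (and Egger slope, when
computable) agree in sign with IVW; a *pleiotropy flag* records
|Egger intercept| ≥ 0.002 or Cochran's Q p < 0.05 but does not by itself
block progression.  A mediator proceeds to MVMR with evidence in at least
one two-step stage and consistency in both; it proceeds to mediation with,
additionally, MVMR evidence for its direct effect and conditional F > 10
for every exposure.  All thresholds are configurable and echoed into each
decision record; decisions are pure functions of estimates plus thresholds.
Per-mediator hard errors are recorded and the pipeline continues — partial
results beat aborts for a screening tool.

## Known limitations

* Wald-ratio and delta-method SEs are first order; second-order options
  are deferred.
* The difference-method SE ignores the (unavailable) covariance between
  the total and direct fits.
* No MR-PRESSO, mode-based estimators, Steiger filtering, MVMR-Egger, or
  liability-threshold outcome model.
* Mediation assumes linearity and no exposure–mediator interaction; on the
  log-odds scale with a common outcome both decompositions carry some
  bias, which is why both are reported and the disagreement is surfaced
  rather than hidden.
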