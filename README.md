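# mrmediation

Mendelian randomization (MR) mediation analysis from GWAS summary
statistics: univariable two-sample MR, two-step MR, multivariable MR
(MVMR) with instrument-strength and pleiotropy diagnostics, and
product/difference mediation decomposition — plus a synthetic GWAS
summary-statistics generator with known truth, so the whole workflow runs
and is testable with no data download.

**Who it is for.** Epidemiologists asking whether an intermediate trait
(a hormone, a reproductive event, a glycaemic measure) *mediates* the
causal effect of an exposure on a disease, when every trait is available
only as per-SNP GWAS effect estimates.  The canonical design: a
protective exposure, a panel of candidate mediators, and a common binary
outcome, screened through a staged prioritisation workflow.

## The statistics at the core

With instruments j carrying exposure effects `bx_j ± se_xj` and outcome
effects `by_j ± se_yj`, the IVW estimate is the zero-intercept weighted
regression of `by` on `bx` with weights `1/se_y²` (per-SNP Wald ratios
`by_j/bx_j` pooled by inverse variance).  MR-Egger adds a free intercept
(directional-pleiotropy probe) after orienting `bx ≥ 0`; the weighted
median interpolates the per-SNP ratios at cumulative weight 0.5.  MVMR
regresses `by` jointly on K exposures' betas, giving *direct* effects,
with conditional F-statistics (instrument strength given the other
exposures; > 10 conventionally adequate) and the Q_A heterogeneity
statistic whose weights carry the exposure-beta uncertainty.

Mediation decomposes the total effect `T` of exposure on outcome via a
mediator into

* product method: `indirect = β₁·β₂` (step-1 effect × MVMR mediator
  direct effect), SE by the delta method
  `√(β₂²se₁² + β₁²se₂²)`;
* difference method: `indirect = T − direct`, flagged conservative for a
  common binary outcome (odds ratios are non-collapsible);
* proportion mediated `indirect/T`.

Everything outcome-side stays on the log-odds scale; odds ratios are
reporting-only.  See `docs/methods.md` for the full model, conventions,
and the synthetic-data generator's structural equations.

## Worked example

Decompose a protective total effect (odds ratio 0.66 per SD of exposure)
through a mediator that the exposure lowers by 0.79 SD and whose direct
odds ratio on the outcome is 0.92, with a direct exposure OR of 0.59:

```python
import numpy as np
from mrmediation import MediationInputs, MREstimate, product_method, difference_method

z = 1.959964
step1      = MREstimate.from_summary(-0.79,        (0.95 - 0.64)/(2*z))
med_direct = MREstimate.from_summary(np.log(0.92), (np.log(0.99) - np.log(0.86))/(2*z), scale="log_odds")
total      = MREstimate.from_summary(np.log(0.66), (np.log(0.76) - np.log(0.57))/(2*z), scale="log_odds")
exp_direct = MREstimate.from_summary(np.log(0.59), 0.08, scale="log_odds")

inputs = MediationInputs(total=total, step1=step1,
                         mediator_direct=med_direct, exposure_direct=exp_direct)
p = product_method(inputs)
d = difference_method(inputs)
print(f"product    indirect={p.indirect:+.4f}  se={p.se:.4f}  95% CI [{p.ci_low:+.4f}, {p.ci_high:+.4f}]")
print(f"difference indirect={d.indirect:+.4f}  se={d.se:.4f}")
print(f"proportion mediated = {p.proportion_mediated.value:.4f}  flags={p.proportion_mediated.flags}")
```

prints

```
product    indirect=+0.0659  se=0.0291  95% CI [+0.0088, +0.1230]
difference indirect=+0.1121  se=0.1086
proportion mediated = -0.1585  flags=['opposing-direction', 'ci-unreliable']
```

Read: the mediated path is *positive* (+0.066 log-odds, CI excluding
zero) while the total effect is protective — the mediator works *against*
the exposure's protection, so the "proportion mediated" is negative and
flagged as not a proportion.  The difference method agrees in sign but is
noisier, as expected for separate fits with the covariance unavailable.

End-to-end on synthetic data, from a shell:

```sh
mrmediation simulate --seed 3 --out study/            # exposure/mediator/outcome TSVs + truth
mrmediation mr --exposure study/exposure.tsv --outcome study/mediator.tsv --out step1.tsv
mrmediation mvmr --exposure study/exposure.tsv --exposure study/mediator.tsv \
    --outcome study/outcome.tsv --outcome-binary --out mvmr.tsv
mrmediation pipeline --config pipeline.yaml           # full staged prioritisation run
```

All tables are tab-separated with documented headers; the pipeline writes
stage tables, a decision table and a run manifest (seeds, thresholds,
version) so a rerun with the same config and seed is byte-identical.

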