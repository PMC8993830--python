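"""Mediation analysis: decompose a total causal effect into direct and indirect parts.

Two-step MR supplies the exposure -> mediator effect (step 1) and MVMR
supplies mediator -> outcome and exposure -> outcome *direct* effects;
mediation then decomposes the univariable total effect:

* Product method: indirect = beta_step1 * beta_mediator_direct, with a
  first-order delta-method SE.
* Difference method: indirect = total - exposure_direct, with the
  covariance between the two fits unavailable and therefore ignored —
  the result is flagged conservative.

All outcome-side arithmetic stays on the log-odds scale for binary
outcomes (odds ratios only at the reporting boundary).  With a common
binary outcome, the non-collapsibility of the odds ratio makes the two
decompositions disagree systematically; the product method is the default
headline estimate here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import IncompleteInputsError, UndefinedProportionError
from .mr import Z95, MREstimate, MRReport, univariable_battery
from .sumstats import (
    CLUMP_R2,
    GWAS_P_THRESHOLD,
    SummaryStats,
    harmonise,
    select_instruments,
)


@dataclass
class MediationInputs:
    """Estimates feeding a mediation decomposition.

    ``total``: univariable exposure -> outcome; ``step1``: univariable
    exposure -> mediator (mediator units); ``mediator_direct`` and
    ``exposure_direct``: MVMR direct effects on the outcome scale.
    Outcome-side estimates must share one scale.
    """

    total: MREstimate | None = None
    step1: MREstimate | None = None
    mediator_direct: MREstimate | None = None
    exposure_direct: MREstimate | None = None

    def __post_init__(self):
        scales = {
            e.scale for e in (self.total, self.mediator_direct, self.exposure_direct)
            if e is not None
        }
        if len(scales) > 1:
            raise ValueError(f"outcome-side estimates mix scales: {scales}")


@dataclass
class ProportionMediated:
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    flags: list = field(default_factory=list)


@dataclass
class MediationResult:
    method: str  # "product" or "difference"
    indirect: float
    se: float
    ci_low: float
    ci_high: float
    proportion_mediated: ProportionMediated | None = None
    flags: list = field(default_factory=list)


def delta_se(b1: float, se1: float, b2: float, se2: float,
             include_cross: bool = False) -> float:
    """First-order delta-method SE of the product b1*b2.

    sqrt(b2^2 se1^2 + b1^2 se2^2), optionally adding the exact-normal
    cross term se1^2 se2^2.
    """
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    v = b2 ** 2 * se1 ** 2 + b1 ** 2 * se2 ** 2
    if include_cross:
        v += se1 ** 2 * se2 ** 2
    return float(np.sqrt(v))


def proportion_mediated(indirect: float, total: float,
                        se_indirect: float | None = None,
                        se_total: float | None = None) -> ProportionMediated:
    """indirect/total, with a delta-method CI on the ratio when SEs are given.

    When indirect and total point in opposite directions the value is not
    a proportion; it is flagged "opposing-direction".
    """
    if total == 0:
        raise UndefinedProportionError("total effect is zero")
    value = indirect / total
    flags = []
    if indirect != 0 and np.sign(indirect) != np.sign(total):
        flags.append("opposing-direction")
    ci_low = ci_high = None
    if se_indirect is not None and se_total is not None:
        # first-order variance of a ratio, covariance ignored
        var = (se_indirect / total) ** 2 + (indirect * se_total / total ** 2) ** 2
        se = float(np.sqrt(var))
        ci_low, ci_high = value - Z95 * se, value + Z95 * se
        if flags:
            flags.append("ci-unreliable")
    return ProportionMediated(float(value), ci_low, ci_high, flags)


def product_method(inputs: MediationInputs, include_cross: bool = False) -> MediationResult:
    """Indirect effect as the product of step-1 and mediator-direct betas."""
    if inputs.step1 is None or inputs.mediator_direct is None:
        raise IncompleteInputsError("product method needs step1 and mediator_direct")
    b1, se1 = inputs.step1.beta, inputs.step1.se
    b2, se2 = inputs.mediator_direct.beta, inputs.mediator_direct.se
    indirect = b1 * b2
    se = delta_se(b1, se1, b2, se2, include_cross=include_cross)
    prop = None
    if inputs.total is not None and inputs.total.beta != 0:
        prop = proportion_mediated(indirect, inputs.total.beta, se, inputs.total.se)
    return MediationResult("product", float(indirect), se,
                           indirect - Z95 * se, indirect + Z95 * se, prop)


def difference_method(inputs: MediationInputs) -> MediationResult:
    """Indirect effect as total minus exposure-direct.

    The covariance between the two estimates (separate fits) is ignored,
    so the SE — and the method itself for common binary outcomes — is
    conservative; the result is flagged accordingly.
    """
    if inputs.total is None or inputs.exposure_direct is None:
        raise IncompleteInputsError("difference method needs total and exposure_direct")
    indirect = inputs.total.beta - inputs.exposure_direct.beta
    se = float(np.sqrt(inputs.total.se ** 2 + inputs.exposure_direct.se ** 2))
    prop = None
    if inputs.total.beta != 0:
        prop = proportion_mediated(indirect, inputs.total.beta, se, inputs.total.se)
    return MediationResult("difference", float(indirect), se,
                           indirect - Z95 * se, indirect + Z95 * se, prop,
                           flags=["covariance-ignored-conservative"])


@dataclass
class TwoStepResult:
    step1: MRReport  # exposure -> mediator
    step2: MRReport  # mediator -> outcome


def run_two_step(exposure: SummaryStats, mediator: SummaryStats,
                 outcome: SummaryStats, p_threshold: float = GWAS_P_THRESHOLD,
                 clump_r2: float = CLUMP_R2, ld=None, model: str = "random",
                 n_boot: int = 1000, seed: int = 0) -> TwoStepResult:
    """Two-step MR: exposure->mediator then mediator->outcome, each with the full battery."""
    exp_inst = select_instruments(exposure, p_threshold, clump_r2, ld)
    h1 = harmonise(exp_inst, mediator)
    step1 = univariable_battery(h1, model=model, n_boot=n_boot, seed=seed)
    med_inst = select_instruments(mediator, p_threshold, clump_r2, ld)
    h2 = harmonise(med_inst, outcome)
    step2 = univariable_battery(h2, model=model, n_boot=n_boot, seed=seed)
    return TwoStepResult(step1, step2)
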