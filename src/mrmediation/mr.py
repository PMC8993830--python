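"""Univariable two-sample MR estimators and sensitivity statistics.

Implements the inverse-variance weighted (IVW) estimator — equivalently a
zero-intercept weighted regression of outcome betas on exposure betas with
weights 1/se_y^2 — together with the pleiotropy-robust MR-Egger and
weighted-median estimators, Cochran's Q heterogeneity, leave-one-out and
single-SNP analyses.

Conventions (standard in summary-data MR, documented in the methods note):

* Wald-ratio SEs are first order: exposure-side uncertainty is ignored.
* The default IVW model is multiplicative random effects for >= 2 SNPs,
  which inflates the fixed-effect SE by sqrt(max(1, Q/(n-1))).
* Two-sided p-values come from the normal distribution, not t.
* 95% CIs use the normal 0.975 quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import (
    CollinearityError,
    EmptySetError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .sumstats import HarmonisedSet

Z95 = float(sps.norm.ppf(0.975))

#: Egger intercepts at or above this magnitude flag directional pleiotropy.
EGGER_INTERCEPT_THRESHOLD = 0.002


@dataclass
class MREstimate:
    """A causal-effect estimate on a stated scale.

    ``scale`` is "linear" (SD outcome units) or "log_odds"; for the latter
    ``exp(beta)`` is the odds ratio per exposure unit.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    scale: str = "linear"

    @classmethod
    def from_summary(cls, beta: float, se: float, method: str = "external",
                     n_snp: int = 0, scale: str = "linear") -> "MREstimate":
        """Build an estimate from a beta and SE (CI and p filled in)."""
        return _estimate(method, beta, se, n_snp, scale)

    @property
    def odds_ratio(self):
        if self.scale != "log_odds":
            raise ValueError("odds ratio only defined on the log-odds scale")
        return float(np.exp(self.beta))

    def ci_excludes_null(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0


@dataclass
class HeterogeneityResult:
    """Cochran's Q over per-SNP ratio estimates, with chi-squared upper-tail p."""

    Q: float
    df: int
    pval: float


@dataclass
class EggerResult:
    """MR-Egger slope and intercept from one weighted regression with intercept."""

    slope: MREstimate
    intercept: MREstimate
    directional_pleiotropy: bool


@dataclass
class IVWResult:
    estimate: MREstimate
    heterogeneity: HeterogeneityResult | None = None


@dataclass
class MRReport:
    """IVW estimate plus the sensitivity battery that the data permit."""

    exposure_name: str
    outcome_name: str
    ivw: MREstimate
    heterogeneity: HeterogeneityResult | None = None
    egger: EggerResult | None = None
    weighted_median: MREstimate | None = None
    leave_one_out: list = field(default_factory=list)


def _estimate(method, beta, se, n_snp, scale) -> MREstimate:
    beta = float(beta)
    se = float(se)
    if se > 0:
        pval = float(2.0 * sps.norm.sf(abs(beta) / se))
        pval = max(pval, np.nextafter(0.0, 1.0))
    else:
        pval = 1.0 if beta == 0 else np.nan
    return MREstimate(method, beta, se, beta - Z95 * se, beta + Z95 * se,
                      pval, int(n_snp), scale)


def wald_ratio(bx, se_x, by, se_y, scale="linear") -> MREstimate:
    """Single-SNP ratio estimate by/bx with first-order SE se_y/|bx|."""
    if bx == 0:
        raise UndefinedRatioError("Wald ratio undefined for bx = 0")
    return _estimate("wald_ratio", by / bx, se_y / abs(bx), 1, scale)


def cochran_q(bx, by, se_y, beta) -> HeterogeneityResult:
    """Q = sum((by - beta*bx)^2 / se_y^2) with df = n - 1."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    se_y = np.asarray(se_y, float)
    Q = float(np.sum((by - beta * bx) ** 2 / se_y ** 2))
    df = len(bx) - 1
    pval = float(sps.chi2.sf(Q, df)) if df > 0 else np.nan
    return HeterogeneityResult(Q, df, pval)


def ivw(h: HarmonisedSet, model: str = "random") -> IVWResult:
    """Inverse-variance weighted estimate.

    A single SNP falls back to the Wald ratio.  With ``model="random"``
    (default) the fixed-effect SE is multiplied by
    sqrt(max(1, Q/(n-1))) — multiplicative random effects.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    n = h.n_snp
    if n == 0:
        raise EmptySetError("no SNPs in harmonised set")
    if n == 1:
        est = wald_ratio(h.bx[0], h.se_x[0], h.by[0], h.se_y[0], h.outcome_scale)
        return IVWResult(est, None)
    bx, by, se_y = h.bx, h.by, h.se_y
    w = 1.0 / se_y ** 2
    denom = float(np.sum(w * bx ** 2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = float(np.sqrt(1.0 / denom))
    het = cochran_q(bx, by, se_y, beta)
    se = se_fixed
    if model == "random":
        se = se_fixed * float(np.sqrt(max(1.0, het.Q / het.df)))
    est = _estimate(f"ivw_{'re' if model == 'random' else 'fe'}",
                    beta, se, n, h.outcome_scale)
    return IVWResult(est, het)


def mr_egger(h: HarmonisedSet,
             intercept_threshold: float = EGGER_INTERCEPT_THRESHOLD) -> EggerResult:
    """MR-Egger regression: weighted fit of by on bx with a free intercept.

    Each SNP is first oriented so bx >= 0 (negating both betas where
    needed), which makes the slope invariant to allele re-labelling.  A
    non-zero intercept (average per-SNP pleiotropic effect) indicates
    directional horizontal pleiotropy; the flag fires when
    ``|intercept| >= intercept_threshold`` or its p-value is below 0.05.
    """
    n = h.n_snp
    if n < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {n}")
    sign = np.where(h.bx < 0, -1.0, 1.0)
    bx = h.bx * sign
    by = h.by * sign
    se_y = h.se_y
    if np.ptp(bx) == 0:
        raise CollinearityError("all exposure betas equal after orientation")
    w = 1.0 / se_y ** 2
    X = np.column_stack([np.ones(n), bx])
    xtwx = X.T @ (w[:, None] * X)
    cov_unit = np.linalg.inv(xtwx)
    coef = cov_unit @ (X.T @ (w * by))
    resid = by - X @ coef
    rss = float(np.sum(w * resid ** 2))
    scale = max(1.0, rss / (n - 2)) if n > 2 else 1.0
    ses = np.sqrt(np.diag(cov_unit) * scale)
    slope = _estimate("egger_slope", coef[1], ses[1], n, h.outcome_scale)
    intercept = _estimate("egger_intercept", coef[0], ses[0], n, h.outcome_scale)
    flag = abs(intercept.beta) >= intercept_threshold or intercept.pval < 0.05
    return EggerResult(slope, intercept, bool(flag))


def _weighted_median(ratios, weights):
    """Weighted median via linear interpolation of cumulative weight midpoints."""
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, r))


def weighted_median(h: HarmonisedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator, consistent when >= 50% of weight is valid.

    Per-SNP ratios r_j = by_j/bx_j are weighted by the inverse variance of
    the ratio (first-order: se(r_j) = se_y_j/|bx_j|).  The SE comes from a
    seeded parametric bootstrap resampling (bx, by) from their SEs.
    """
    n = h.n_snp
    if n < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {n}")
    bx, se_x, by, se_y = h.bx, h.se_x, h.by, h.se_y
    ratios = by / bx
    weights = (bx / se_y) ** 2
    point = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    bxb = bx + rng.normal(0.0, 1.0, (n_boot, n)) * se_x
    byb = by + rng.normal(0.0, 1.0, (n_boot, n)) * se_y
    boots = np.empty(n_boot)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(n_boot):
            b = bxb[i]
            boots[i] = _weighted_median(byb[i] / b, (b / se_y) ** 2)
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", point, se, n, h.outcome_scale)


def leave_one_out(h: HarmonisedSet, model: str = "random"):
    """One IVW estimate per omitted SNP: [(omitted snp_id, MREstimate), ...]."""
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("leave-one-out needs >= 2 SNPs")
    out = []
    for sid in h.snp_ids:
        out.append((sid, ivw(h.drop_snp(sid), model=model).estimate))
    return out


def single_snp_estimates(h: HarmonisedSet):
    """Wald ratio per SNP (forest/funnel plot input): [(snp_id, MREstimate), ...]."""
    return [
        (sid, wald_ratio(bx, sx, by, sy, h.outcome_scale))
        for sid, bx, sx, by, sy in zip(h.snp_ids, h.bx, h.se_x, h.by, h.se_y)
    ]


def univariable_battery(h: HarmonisedSet, model: str = "random",
                        n_boot: int = 1000, seed: int = 0,
                        with_loo: bool = False) -> MRReport:
    """IVW plus whatever sensitivity analyses the SNP count permits."""
    res = ivw(h, model=model)
    report = MRReport(h.exposure_name, h.outcome_name, res.estimate, res.heterogeneity)
    if h.n_snp >= 3:
        try:
            report.egger = mr_egger(h)
        except CollinearityError:
            report.egger = None
        report.weighted_median = weighted_median(h, n_boot=n_boot, seed=seed)
    if with_loo and h.n_snp >= 2:
        report.leave_one_out = leave_one_out(h, model=model)
    return report
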