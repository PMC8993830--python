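"""Synthetic GWAS summary statistics from an explicit structural model with known truth.

The generative model mirrors the data structure of a mediation MR study:
a quantitative exposure X (SD units), a quantitative mediator Z, and a
common binary outcome Y, with

    X = G alpha + c_x U + e_x                (standardised)
    Z = theta X + G gamma + c_z U + e_z      (standardised)
    logit P(Y=1) = b0 + delta X + tau Z + G pi + c_y U   (binary outcome)
    Y = delta X + tau Z + G pi + c_y U + e_y             (continuous variant)

where G holds unlinked biallelic SNP dosages (the post-clumping world), U
is a standard-normal confounder, alpha/gamma are block-specific
instrument effects, and pi is direct SNP -> outcome (horizontal
pleiotropy).  b0 is calibrated by bisection on a pilot draw so the case
fraction hits its target (default 53.7%, a common outcome).  Per-SNP
summary statistics are produced by simple linear regression
(quantitative traits, after a rank-based inverse-normal transform) or
univariate logistic regression (binary outcome), exactly the per-SNP
models whose output the estimators consume.

Sample designs: ``disjoint`` (independent cohorts per trait),
``overlap(f)`` (exposure and mediator GWAS share a fraction f of
individuals — f=1 reproduces a fully shared biobank), and ``split`` (one
cohort halved: instrument discovery and exposure betas from half A,
mediator/outcome betas from half B) for winner's-curse comparisons.

Everything is deterministic given (config, seed): the same seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import expit, logit

from .exceptions import ConfigurationError, DegenerateInputError
from .sumstats import SummaryStats, write_summary_stats

_TINY_P = np.nextafter(0.0, 1.0)

# ordered allele pairs excluding strand-ambiguous (palindromic) combinations
_ALLELE_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT"
    if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})
]


@dataclass
class SimConfig:
    """Generative-model parameters; defaults are the package's study conditions.

    Effect sizes: ``theta`` exposure->mediator (SD/SD), ``delta``
    exposure->outcome direct and ``tau`` mediator->outcome (log-odds per
    SD for the binary outcome), ``pi_mean``/``pi_sd`` direct SNP->outcome
    effects on the pleiotropic block.  Per-SNP instrument effects are
    drawn N(0, h2/m) on the standardised-genotype scale.  The defaults
    echo a protective exposure acting partly through a hormone-like
    mediator: theta = -0.24, tau = ln(1.08), and delta chosen so that
    delta + theta*tau = ln(0.66).
    """

    n: int = 20_000
    m_exposure: int = 150
    m_mediator: int = 100
    m_pleiotropic: int = 0
    maf_range: tuple = (0.05, 0.5)
    h2_exposure: float = 0.35
    h2_mediator: float = 0.30
    theta: float = -0.24
    delta: float = float(np.log(0.66) - (-0.24) * np.log(1.08))
    tau: float = float(np.log(1.08))
    pi_mean: float = 0.0
    pi_sd: float = 0.0
    c_x: float = 0.25
    c_z: float = 0.25
    c_y: float = 0.25
    case_fraction: float = 0.537
    b0: float | None = None
    outcome_type: str = "binary"
    design: str = "disjoint"
    overlap: float = 1.0
    rint: bool = True
    seed: int = 0

    def validate(self):
        lo, hi = self.maf_range
        if not (0.01 <= lo < hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0.01 <= lo < hi <= 0.5")
        if self.outcome_type not in ("binary", "continuous"):
            raise ConfigurationError("outcome_type must be binary or continuous")
        if self.design not in ("disjoint", "overlap", "split"):
            raise ConfigurationError("design must be disjoint, overlap or split")
        if not 0.0 <= self.overlap <= 1.0:
            raise ConfigurationError("overlap fraction must be in [0,1]")
        if not 0.0 < self.case_fraction < 1.0:
            raise ConfigurationError("case_fraction must be in (0,1)")
        if self.m_exposure + self.m_mediator + self.m_pleiotropic < 1:
            raise ConfigurationError("need at least one SNP")


@dataclass
class SnpEffects:
    """True per-SNP effects on the standardised-genotype scale."""

    alpha: np.ndarray  # SNP -> exposure
    gamma: np.ndarray  # SNP -> mediator (direct)
    pi: np.ndarray     # SNP -> outcome (horizontal pleiotropy)
    block: np.ndarray  # "exposure" / "mediator" / "pleiotropic"

    @property
    def m_total(self) -> int:
        return len(self.alpha)


@dataclass
class SimTruth:
    """Generative truth for parameter-recovery testing."""

    total_effect: float
    indirect_effect: float
    direct_effect: float
    theta: float
    tau: float
    delta: float
    scale: str
    b0: float | None = None
    per_snp: pd.DataFrame | None = None


@dataclass
class DesignPlan:
    """Which pool individuals contribute to which GWAS role."""

    design: str
    overlap: float
    pool_n: int
    subsets: dict  # role -> index array

    def subset(self, role: str) -> np.ndarray:
        return self.subsets[role]


@dataclass
class SimOutput:
    config: SimConfig
    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    truth: SimTruth
    design: DesignPlan
    label_flips: dict = field(default_factory=dict)  # trait -> flipped-SNP mask


def _rng(seed):
    """Accept an int seed, a SeedSequence or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(n: int, m: int, maf_range=(0.05, 0.5), seed=0):
    """Unlinked biallelic dosages: counts Binomial(2, maf_j), maf_j ~ U(range).

    Returns ``(G, mafs)`` with G of shape (n, m); m = 0 yields an empty
    matrix that downstream operations accept (pure-noise traits).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    mafs = rng.uniform(maf_range[0], maf_range[1], m)
    return _genotypes_given_mafs(rng, n, mafs), mafs


def _genotypes_given_mafs(rng, n, mafs):
    # sum of two Bernoulli(maf) draws == Binomial(2, maf); float32 uniforms
    # halve the memory traffic of the draw
    m = len(mafs)
    maf32 = np.asarray(mafs, np.float32)
    G = (rng.random((n, m), dtype=np.float32) < maf32).astype(np.float64)
    G += rng.random((n, m), dtype=np.float32) < maf32
    return G


def rank_inverse_normal(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset c = 3/8.

    Maps ranks through Phi^-1((rank - 3/8)/(n + 1/4)); ties get average
    ranks.  This is how biobank-scale quantitative GWAS put traits on an
    SD scale prior to regression.
    """
    x = np.asarray(values, float)
    if np.unique(x).size < 2:
        raise DegenerateInputError("rank inverse normal needs >= 2 distinct values")
    ranks = sps.rankdata(x, method="average")
    return sps.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


def draw_effects(config: SimConfig, seed=0) -> SnpEffects:
    """Draw block-structured per-SNP true effects for one replicate."""
    rng = _rng(seed)
    me, mm, mp = config.m_exposure, config.m_mediator, config.m_pleiotropic
    m = me + mm + mp
    alpha = np.zeros(m)
    gamma = np.zeros(m)
    pi = np.zeros(m)
    block = np.array(["exposure"] * me + ["mediator"] * mm + ["pleiotropic"] * mp)
    n_exp_like = me + mp
    if n_exp_like and config.h2_exposure > 0:
        sd = np.sqrt(config.h2_exposure / n_exp_like)
        draws = rng.normal(0.0, sd, n_exp_like)
        alpha[:me] = draws[:me]
        alpha[me + mm:] = draws[me:]
    if mm and config.h2_mediator > 0:
        gamma[me:me + mm] = rng.normal(0.0, np.sqrt(config.h2_mediator / mm), mm)
    if mp:
        # directional pleiotropy is defined relative to the exposure-raising
        # allele (otherwise random allele orientation would cancel it)
        draws = rng.normal(config.pi_mean, config.pi_sd, mp)
        pi[me + mm:] = np.where(alpha[me + mm:] < 0, -draws, draws)
    return SnpEffects(alpha, gamma, pi, block)


def _standardise_genotypes(G, mafs):
    sd = np.sqrt(2.0 * mafs * (1.0 - mafs))
    return (G - 2.0 * mafs) / sd


def _gs_dot(G, mafs, vec):
    """(standardised G) @ vec without materialising the standardised matrix."""
    n = G.shape[0]
    vec = np.asarray(vec, float)
    if vec.size == 0 or not np.any(vec):
        return np.zeros(n)
    w = vec / np.sqrt(2.0 * mafs * (1.0 - mafs))
    return G @ w - float(np.sum(2.0 * mafs * w))


def _noise_sd(explained: float) -> float:
    return float(np.sqrt(max(0.05, 1.0 - explained)))


def simulate_phenotypes(G, mafs, effects: SnpEffects, config: SimConfig,
                        seed=0, b0: float | None = None):
    """Generate (X, Z, Y, U) for the pool individuals in G.

    X and Z are standardised to unit variance before entering the outcome
    model (SD-unit convention).  For a binary outcome ``b0`` must be
    supplied (see :func:`calibrate_b0`) unless the linear predictor is
    degenerate, in which case logit(case_fraction) is exact.
    """
    rng = _rng(seed)
    n = G.shape[0]
    U = rng.normal(0.0, 1.0, n)

    gx = _gs_dot(G, mafs, effects.alpha)
    var_gx = float(np.sum(effects.alpha ** 2))
    X = gx + config.c_x * U + rng.normal(0.0, _noise_sd(var_gx + config.c_x ** 2), n)
    X = (X - X.mean()) / X.std()

    gz = _gs_dot(G, mafs, effects.gamma)
    var_gz = float(np.sum(effects.gamma ** 2))
    Z = config.theta * X + gz + config.c_z * U \
        + rng.normal(0.0, _noise_sd(config.theta ** 2 + var_gz + config.c_z ** 2), n)
    Z = (Z - Z.mean()) / Z.std()

    lin = config.delta * X + config.tau * Z + _gs_dot(G, mafs, effects.pi) \
        + config.c_y * U
    if config.outcome_type == "binary":
        if b0 is None:
            if _null_outcome(config, effects):
                b0 = float(logit(config.case_fraction))
            else:
                raise ConfigurationError(
                    "binary outcome needs b0 (use calibrate_b0 or SimConfig.b0)"
                )
        Y = (rng.random(n) < expit(b0 + lin)).astype(np.float64)
    else:
        Y = lin + rng.normal(0.0, 1.0, n)
    return X, Z, Y, U


def _null_outcome(config: SimConfig, effects: SnpEffects) -> bool:
    return (config.delta == 0 and config.tau == 0 and config.c_y == 0
            and not np.any(effects.pi))


def calibrate_b0(config: SimConfig, effects: SnpEffects, seed=0,
                 n_pilot: int = 200_000):
    """Calibrate the baseline log-odds b0 by bisection on a pilot draw.

    Returns ``(b0, total_log_odds)``: b0 hits the target case fraction
    (tolerance well inside +-0.02 at pilot scale) and the second value is
    the marginal causal total effect of a +1 SD exposure shift on the
    log-odds scale, logit(E[sigmoid(b0 + s + delta + theta*tau)]) -
    logit(E[sigmoid(b0 + s)]), evaluated on the same pilot.
    """
    if _null_outcome(config, effects):
        return float(logit(config.case_fraction)), 0.0
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    kids = ss.spawn(2) if hasattr(ss, "spawn") else [ss, ss]
    G, mafs = simulate_genotypes(n_pilot, effects.m_total, config.maf_range, kids[0])
    rng = _rng(kids[1])
    U = rng.normal(0.0, 1.0, n_pilot)
    gx = _gs_dot(G, mafs, effects.alpha)
    var_gx = float(np.sum(effects.alpha ** 2))
    X = gx + config.c_x * U + rng.normal(0.0, _noise_sd(var_gx + config.c_x ** 2), n_pilot)
    X = (X - X.mean()) / X.std()
    gz = _gs_dot(G, mafs, effects.gamma)
    var_gz = float(np.sum(effects.gamma ** 2))
    Z = config.theta * X + gz + config.c_z * U \
        + rng.normal(0.0, _noise_sd(config.theta ** 2 + var_gz + config.c_z ** 2),
                     n_pilot)
    Z = (Z - Z.mean()) / Z.std()
    s = config.delta * X + config.tau * Z + _gs_dot(G, mafs, effects.pi) \
        + config.c_y * U

    target = config.case_fraction
    b0 = float(optimize.brentq(lambda b: expit(b + s).mean() - target, -20.0, 20.0,
                               xtol=1e-10))
    shift = config.delta + config.theta * config.tau
    p0 = expit(b0 + s).mean()
    p1 = expit(b0 + s + shift).mean()
    total = float(logit(p1) - logit(p0))
    return b0, total


def _linear_gwas(y, G):
    """Vectorised per-SNP simple linear regression; returns (beta, se, p)."""
    n = len(y)
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    ok = sxx > 0
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    p = np.full(G.shape[1], np.nan)
    sxy = Gc.T @ yc
    beta[ok] = sxy[ok] / sxx[ok]
    syy = float(yc @ yc)
    rss = syy - beta[ok] ** 2 * sxx[ok]
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se[ok] = np.sqrt(sigma2 / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[ok] / se[ok]
    p[ok] = np.maximum(2.0 * sps.t.sf(np.abs(tstat), n - 2), _TINY_P)
    return beta, se, p


def _newton_pass(y, G, G2, b0, b1, ok, dtype):
    eta = b0 + G * b1
    np.clip(eta, -30.0, 30.0, out=eta)
    mu = expit(eta)
    r = y[:, None] - mu
    w = mu * (1.0 - mu)
    g0 = r.sum(axis=0, dtype=dtype)
    g1 = np.einsum("ij,ij->j", r, G)
    h00 = w.sum(axis=0, dtype=dtype)
    h01 = np.einsum("ij,ij->j", w, G)
    h11 = np.einsum("ij,ij->j", w, G2)
    det = h00 * h11 - h01 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        db0 = np.where(ok & (det > 0), (h11 * g0 - h01 * g1) / det, 0.0)
        db1 = np.where(ok & (det > 0), (h00 * g1 - h01 * g0) / det, 0.0)
    return db0, db1, det, h00


def _logistic_gwas(y, G, max_iter: int = 30):
    """Vectorised per-SNP univariate logistic regression (Newton-Raphson).

    Each SNP gets its own (intercept, slope) fit of y on dosage, warm
    started from the linear-probability approximation; iterations run in
    float32 with a final float64 Newton polish, from which the Wald SEs
    are taken.  Monomorphic SNPs return NaN.
    """
    n, m = G.shape
    ybar = float(np.mean(y))
    if ybar in (0.0, 1.0):
        raise DegenerateInputError("outcome has no variation")
    gbar = G.mean(axis=0)
    ok = G.var(axis=0) > 0
    # linear-probability warm start: logistic slope ~ linear slope / (p(1-p))
    lin_beta, _, _ = _linear_gwas(y, G)
    b1 = np.where(ok & np.isfinite(lin_beta), lin_beta / (ybar * (1 - ybar)), 0.0)
    b0 = float(logit(ybar)) - b1 * gbar

    Gf = G.astype(np.float32)
    G2f = Gf * Gf
    yf = np.asarray(y, np.float32)
    b0f = b0.astype(np.float32)
    b1f = b1.astype(np.float32)
    for _ in range(max_iter):
        db0, db1, _, _ = _newton_pass(yf, Gf, G2f, b0f, b1f, ok, np.float32)
        b0f += db0
        b1f += db1
        if max(np.abs(db0).max(initial=0.0), np.abs(db1).max(initial=0.0)) < 1e-4:
            break
    # one float64 polish step; SEs from the observed information there
    b0 = b0f.astype(np.float64)
    b1 = b1f.astype(np.float64)
    G2 = G * G
    for _ in range(3):
        db0, db1, det, h00 = _newton_pass(y, G, G2, b0, b1, ok, np.float64)
        b0 += db0
        b1 += db1
        if max(np.abs(db0).max(initial=0.0), np.abs(db1).max(initial=0.0)) < 1e-10:
            break
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, h00 / det, np.nan))
        z = b1 / se
    beta = np.where(ok, b1, np.nan)
    se = np.where(ok, se, np.nan)
    p = np.maximum(2.0 * sps.norm.sf(np.abs(z)), _TINY_P)
    p = np.where(ok, p, np.nan)
    return beta, se, p


def default_snp_meta(m: int, seed=0) -> pd.DataFrame:
    """Sequential rs-ids with random non-palindromic allele pairs."""
    rng = _rng(seed)
    pick = rng.integers(0, len(_ALLELE_PAIRS), m)
    return pd.DataFrame({
        "SNP": [f"rs{i + 1}" for i in range(m)],
        "CHR": "1",
        "POS": np.arange(1, m + 1, dtype=np.int64) * 1000,
        "EA": [_ALLELE_PAIRS[k][0] for k in pick],
        "OA": [_ALLELE_PAIRS[k][1] for k in pick],
    })


def compute_association_stats(values, G, trait_type: str, subset=None,
                              snp_meta: pd.DataFrame | None = None,
                              trait_name: str = "trait", unit: str = "SD") -> SummaryStats:
    """Per-SNP GWAS of a trait on genotype over a sample subset.

    Quantitative traits use simple linear regression, binary traits
    univariate logistic regression; the effect allele is the counted
    allele.  Monomorphic SNPs in the subset are dropped with a reason.
    """
    values = np.asarray(values, float)
    if subset is not None:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise ValueError("empty sample subset")
        y = values[subset]
        Gsub = G[subset]
    else:
        y = values
        Gsub = G
    n, m = Gsub.shape
    if snp_meta is None:
        meta = default_snp_meta(m, seed=0)
    else:
        meta = snp_meta.reset_index(drop=True)
    if trait_type == "binary":
        beta, se, p = _logistic_gwas(y, Gsub)
        unit = "logOR"
    else:
        beta, se, p = _linear_gwas(y, Gsub)
    eaf = Gsub.mean(axis=0) / 2.0
    table = pd.DataFrame({
        "SNP": meta["SNP"], "CHR": meta["CHR"], "POS": meta["POS"],
        "EA": meta["EA"], "OA": meta["OA"],
        "EAF": eaf, "BETA": beta, "SE": se, "P": p,
        "N": np.full(m, n, dtype=np.int64),
    })
    bad = ~np.isfinite(beta) | ~np.isfinite(se) | (se <= 0)
    dropped = [(sid, "monomorphic") for sid in table.loc[bad, "SNP"]]
    table = table[~bad].reset_index(drop=True)
    return SummaryStats(trait_name, table, trait_type, unit, dropped=dropped)


def make_design(n: int, design: str, seed=0, overlap: float = 1.0) -> DesignPlan:
    """Assign pool individuals to GWAS roles (exposure/mediator/outcome).

    ``disjoint``: three independent cohorts of n.  ``overlap``: exposure
    and mediator GWAS share round(overlap*n) individuals; the outcome
    cohort is always disjoint.  ``split``: one cohort of n randomly
    halved — half A provides instrument discovery and exposure betas,
    half B the mediator and outcome betas.
    """
    if design == "disjoint":
        overlap = 0.0
    if design in ("disjoint", "overlap"):
        if n < 1:
            raise ConfigurationError("n must be >= 1")
        shared = int(round(overlap * n))
        subsets = {
            "exposure": np.arange(0, n),
            "mediator": np.arange(n - shared, 2 * n - shared),
            "outcome": np.arange(2 * n - shared, 3 * n - shared),
        }
        return DesignPlan(design, overlap, 3 * n - shared, subsets)
    if design == "split":
        half = n // 2
        if half < 1000 or (n - half) < 1000:
            raise ConfigurationError(
                f"split design needs both halves >= 1000 individuals (n={n})"
            )
        perm = _rng(seed).permutation(n)
        a, b = np.sort(perm[:half]), np.sort(perm[half:])
        return DesignPlan(design, 0.0, n,
                          {"exposure": a, "mediator": b, "outcome": b})
    raise ConfigurationError(f"unknown design {design!r}")


def flip_allele_labels(stats: SummaryStats, mask) -> SummaryStats:
    """Re-express records on the other allele (EA<->OA, beta negated, EAF complemented).

    A statistically neutral relabelling used to exercise harmonisation.
    """
    t = stats.table.copy()
    mask = np.asarray(mask, bool)
    ea = t.loc[mask, "EA"].copy()
    t.loc[mask, "EA"] = t.loc[mask, "OA"]
    t.loc[mask, "OA"] = ea
    t.loc[mask, "BETA"] = -t.loc[mask, "BETA"]
    t.loc[mask, "EAF"] = 1.0 - t.loc[mask, "EAF"]
    return SummaryStats(stats.trait_name, t, stats.trait_type, stats.unit,
                        dropped=list(stats.dropped))


def _per_snp_truth(effects: SnpEffects, mafs, meta: pd.DataFrame) -> pd.DataFrame:
    sd = np.sqrt(2.0 * mafs * (1.0 - mafs))
    return pd.DataFrame({
        "SNP": meta["SNP"], "block": effects.block, "maf": mafs,
        "alpha_std": effects.alpha, "gamma_std": effects.gamma,
        "pi_std": effects.pi,
        "alpha_allele": effects.alpha / sd,
        "gamma_allele": effects.gamma / sd,
        "pi_allele": effects.pi / sd,
    })


def simulate_study(config: SimConfig) -> SimOutput:
    """End-to-end: effects -> genotypes -> phenotypes -> three GWAS + truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    k_eff, k_design, k_geno, k_pheno, k_calib, k_alleles = ss.spawn(6)
    effects = draw_effects(config, k_eff)
    plan = make_design(config.n, config.design, k_design, config.overlap)
    G, mafs = simulate_genotypes(plan.pool_n, effects.m_total, config.maf_range, k_geno)

    b0 = config.b0
    if config.outcome_type == "binary":
        cal_b0, total = calibrate_b0(config, effects, k_calib)
        if b0 is None:
            b0 = cal_b0
        scale = "log_odds"
    else:
        total = config.delta + config.theta * config.tau
        scale = "linear"
    X, Z, Y, _ = simulate_phenotypes(G, mafs, effects, config, k_pheno, b0=b0)

    rng_alleles = _rng(k_alleles)
    meta = default_snp_meta(effects.m_total, rng_alleles)

    def gwas(values, role, name, trait_type, rint):
        vals = values
        if rint:
            vals = values.copy()
            sub = plan.subset(role)
            vals[sub] = rank_inverse_normal(values[sub])
        stats = compute_association_stats(vals, G, trait_type, plan.subset(role),
                                          meta, trait_name=name)
        mask = rng_alleles.random(len(stats.table)) < 0.5
        return flip_allele_labels(stats, mask), mask

    exposure, flip_x = gwas(X, "exposure", "exposure", "quantitative", config.rint)
    mediator, flip_z = gwas(Z, "mediator", "mediator", "quantitative", config.rint)
    out_type = "binary" if config.outcome_type == "binary" else "quantitative"
    outcome, flip_y = gwas(Y, "outcome", "outcome", out_type, False)

    truth = SimTruth(
        total_effect=total,
        indirect_effect=config.theta * config.tau,
        direct_effect=config.delta,
        theta=config.theta, tau=config.tau, delta=config.delta,
        scale=scale, b0=b0,
        per_snp=_per_snp_truth(effects, mafs, meta),
    )
    return SimOutput(config, exposure, mediator, outcome, truth, plan,
                     label_flips={"exposure": flip_x, "mediator": flip_z,
                                  "outcome": flip_y})


@dataclass
class FastStudy:
    """Economy replicate: full exposure/mediator GWAS, outcome GWAS at candidates only."""

    config: SimConfig
    truth: SimTruth
    exposure: SummaryStats
    mediator: SummaryStats | None
    outcome: SummaryStats
    candidate_snps: list


def simulate_study_fast(config: SimConfig, p_threshold: float = 5e-8,
                        with_mediator: bool = True) -> FastStudy:
    """One disjoint-design replicate tuned for replicated experiments.

    Identical generative model to :func:`simulate_study` with three
    economies: the three cohorts share the population MAFs and effect
    draws (as disjoint samples from one population should), allele labels
    are kept in the reference orientation, and the outcome GWAS — the
    expensive per-SNP logistic fit — is computed only at SNPs passing
    instrument selection for the exposure or the mediator, since
    downstream MR consumes nothing else.  For a binary outcome the
    baseline ``b0`` must be resolvable without a pilot draw (a null
    outcome model, or ``config.b0`` set from :func:`calibrate_b0`); the
    true total effect is exact for the continuous variant and for the
    null, and NaN otherwise.
    """
    config.validate()
    if config.design != "disjoint":
        raise ConfigurationError("simulate_study_fast supports the disjoint design only")
    ss = np.random.SeedSequence(config.seed)
    k_eff, k_maf, k_a, k_b, k_c = ss.spawn(5)
    effects = draw_effects(config, k_eff)
    m = effects.m_total
    mafs = _rng(k_maf).uniform(config.maf_range[0], config.maf_range[1], m)
    meta = default_snp_meta(m, seed=0)

    b0 = config.b0
    null = _null_outcome(config, effects)
    if config.outcome_type == "binary":
        if b0 is None:
            if not null:
                raise ConfigurationError(
                    "simulate_study_fast needs SimConfig.b0 for a non-null binary outcome"
                )
            b0 = float(logit(config.case_fraction))
        total = 0.0 if null else np.nan
        scale = "log_odds"
    else:
        total = config.delta + config.theta * config.tau
        scale = "linear"

    def cohort(seed):
        kg, kp = seed.spawn(2)
        G = _genotypes_given_mafs(_rng(kg), config.n, mafs)
        X, Z, Y, _ = simulate_phenotypes(G, mafs, effects, config, kp, b0=b0)
        return G, X, Z, Y

    def quant_gwas(values, G, name):
        v = rank_inverse_normal(values) if config.rint else values
        return compute_association_stats(v, G, "quantitative", None, meta,
                                         trait_name=name)

    G_a, X_a, _, _ = cohort(k_a)
    exposure = quant_gwas(X_a, G_a, "exposure")
    sel = set(exposure.table.loc[exposure.table["P"] < p_threshold, "SNP"])

    mediator = None
    if with_mediator:
        G_b, _, Z_b, _ = cohort(k_b)
        mediator = quant_gwas(Z_b, G_b, "mediator")
        sel |= set(mediator.table.loc[mediator.table["P"] < p_threshold, "SNP"])

    candidates = sorted(sel, key=lambda s: int(s[2:]))
    cols = [int(s[2:]) - 1 for s in candidates]
    out_type = "binary" if config.outcome_type == "binary" else "quantitative"
    if config.delta == 0 and config.tau == 0:
        # outcome independent of X and Z: only the candidate (and pleiotropic)
        # genotype columns can touch it, so generate just those
        need = sorted(set(cols) | set(np.nonzero(effects.pi)[0]))
        kg, kp = k_c.spawn(2)
        G_c = _genotypes_given_mafs(_rng(kg), config.n, mafs[need])
        rng_c = _rng(kp)
        U_c = rng_c.normal(0.0, 1.0, config.n)
        lin = _gs_dot(G_c, mafs[need], effects.pi[need]) + config.c_y * U_c
        if config.outcome_type == "binary":
            Y_c = (rng_c.random(config.n) < expit(b0 + lin)).astype(np.float64)
        else:
            Y_c = lin + rng_c.normal(0.0, 1.0, config.n)
        sub = [need.index(c) for c in cols]
        G_cand = G_c[:, sub]
    else:
        G_c, _, _, Y_c = cohort(k_c)
        G_cand = G_c[:, cols]
    outcome = compute_association_stats(
        Y_c, G_cand, out_type, None,
        meta.iloc[cols].reset_index(drop=True), trait_name="outcome",
    )
    truth = SimTruth(total, config.theta * config.tau, config.delta,
                     config.theta, config.tau, config.delta, scale, b0,
                     per_snp=_per_snp_truth(effects, mafs, meta))
    return FastStudy(config, truth, exposure, mediator, outcome, candidates)


def write_study(sim: SimOutput, outdir) -> dict:
    """Write a study to disk: three sumstats TSVs, per-SNP truth TSV, truth/config JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("exposure", "mediator", "outcome"):
        p = outdir / f"{name}.tsv"
        write_summary_stats(getattr(sim, name), p)
        paths[name] = p
    snp_path = outdir / "truth_snps.tsv"
    sim.truth.per_snp.to_csv(snp_path, sep="\t", index=False)
    paths["truth_snps"] = snp_path
    summary = {
        "total_effect": sim.truth.total_effect,
        "indirect_effect": sim.truth.indirect_effect,
        "direct_effect": sim.truth.direct_effect,
        "theta": sim.truth.theta, "tau": sim.truth.tau, "delta": sim.truth.delta,
        "scale": sim.truth.scale, "b0": sim.truth.b0,
        "design": sim.design.design, "overlap": sim.design.overlap,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(sim.config).items()},
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    paths["truth"] = truth_path
    return paths
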