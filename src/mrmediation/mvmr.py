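"""Multivariable MR: joint direct-effect estimation with strength and pleiotropy diagnostics.

Multivariable MR (MVMR) regresses outcome betas jointly on K exposures'
betas across the union of their instruments, estimating each exposure's
*direct* effect conditional on the others.  Alongside the IVW-style
estimator this module provides the diagnostics used to gate downstream
mediation analysis:

* ``q_a`` — the Q_A heterogeneity statistic, a multivariable analogue of
  Cochran's Q whose weights account for exposure-beta uncertainty (and,
  optionally, the phenotypic covariance between exposures measured in the
  same cohort);
* ``conditional_f`` — per-exposure conditional F-statistics (instrument
  strength given the other exposures; > 10 is conventionally "strong");
* ``pheno_corr_from_sumstats`` — phenotypic correlation estimated from the
  correlation of null-SNP z-scores between same-cohort GWAS;
* ``qhet_estimate`` — the Q-minimisation (Q-het) estimator, which chooses
  the effect vector minimising Q_A and is used when weak instruments or
  heterogeneity make the IVW fit doubtful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .exceptions import (
    CollinearityError,
    ConvergenceError,
    DegenerateWeightError,
    InsufficientDataError,
    UnderIdentifiedError,
)
from .mr import HeterogeneityResult, MREstimate, _estimate
from .sumstats import (
    CLUMP_R2,
    GWAS_P_THRESHOLD,
    PALINDROME_EAF_WINDOW,
    LDInfo,
    SummaryStats,
    align_record,
    select_instruments,
)

#: Conventional conditional-F threshold for adequate instrument strength.
CONDITIONAL_F_THRESHOLD = 10.0


@dataclass
class MVHarmonisedSet:
    """K exposures' and one outcome's effects, aligned to a single effect allele per SNP."""

    exposure_names: list
    outcome_name: str
    table: pd.DataFrame  # snp_id, bx_<name>..., se_<name>..., by, se_y
    provenance: dict = field(default_factory=dict)  # snp_id -> exposures that selected it
    dropped: list = field(default_factory=list)
    outcome_scale: str = "linear"

    @property
    def n_snp(self) -> int:
        return len(self.table)

    @property
    def K(self) -> int:
        return len(self.exposure_names)

    @property
    def bx_matrix(self):
        return np.column_stack([
            self.table[f"bx_{n}"].to_numpy(float) for n in self.exposure_names
        ])

    @property
    def se_x_matrix(self):
        return np.column_stack([
            self.table[f"se_{n}"].to_numpy(float) for n in self.exposure_names
        ])

    @property
    def by(self):
        return self.table["by"].to_numpy(float)

    @property
    def se_y(self):
        return self.table["se_y"].to_numpy(float)

    @classmethod
    def from_arrays(cls, bx, by, se_y, se_x=None, exposure_names=None,
                    snp_ids=None, outcome_name="outcome",
                    outcome_scale="linear") -> "MVHarmonisedSet":
        bx = np.atleast_2d(np.asarray(bx, float))
        n, K = bx.shape
        by = np.asarray(by, float)
        se_y = np.asarray(se_y, float)
        se_x = np.zeros_like(bx) if se_x is None else np.asarray(se_x, float)
        if exposure_names is None:
            exposure_names = [f"exposure{k}" for k in range(K)]
        if snp_ids is None:
            snp_ids = [f"snp{i}" for i in range(n)]
        data = {"snp_id": list(snp_ids)}
        for k, name in enumerate(exposure_names):
            data[f"bx_{name}"] = bx[:, k]
            data[f"se_{name}"] = se_x[:, k]
        data["by"] = by
        data["se_y"] = se_y
        return cls(list(exposure_names), outcome_name, pd.DataFrame(data),
                   outcome_scale=outcome_scale)

    def resample(self, idx) -> "MVHarmonisedSet":
        t = self.table.iloc[np.asarray(idx)].reset_index(drop=True)
        return MVHarmonisedSet(self.exposure_names, self.outcome_name, t,
                               outcome_scale=self.outcome_scale)


@dataclass
class PhenoCorrMatrix:
    """Phenotypic correlation between traits estimated from null-SNP z-scores."""

    trait_names: list
    matrix: np.ndarray
    n_snps_used: int = 0

    def corr(self, a: str, b: str) -> float:
        i = self.trait_names.index(a)
        j = self.trait_names.index(b)
        return float(self.matrix[i, j])

    @classmethod
    def identity(cls, names) -> "PhenoCorrMatrix":
        names = list(names)
        return cls(names, np.eye(len(names)), 0)


@dataclass
class MVMRResult:
    exposure_names: list
    estimates: list  # MREstimate per exposure
    q_a: HeterogeneityResult | None = None
    conditional_f: np.ndarray | None = None

    def estimate_for(self, name: str) -> MREstimate:
        return self.estimates[self.exposure_names.index(name)]


def build_mv_set(exposures, outcome: SummaryStats,
                 p_threshold: float = GWAS_P_THRESHOLD,
                 clump_r2: float = CLUMP_R2, ld: LDInfo | None = None,
                 palindrome_eaf_window: float = PALINDROME_EAF_WINDOW) -> MVHarmonisedSet:
    """Union-of-instruments construction for MVMR.

    Instruments are selected per exposure, pooled (de-duplicated), clumped
    across the union (p for clumping = best p across exposures), then each
    trait is aligned to the outcome's allele frame.  SNPs missing from any
    trait, or unresolvable there, are dropped with a reason.
    """
    exposures = list(exposures)
    if len(exposures) < 2:
        raise ValueError("build_mv_set needs >= 2 exposures (use harmonise for one)")
    names = [e.trait_name for e in exposures]
    if len(set(names)) != len(names):
        raise ValueError("exposure trait names must be unique")

    provenance = {}
    best_p = {}
    for e in exposures:
        sel = select_instruments(e, p_threshold=p_threshold, clump_r2=clump_r2, ld=ld)
        for r in sel.table.itertuples():
            provenance.setdefault(r.SNP, []).append(e.trait_name)
            best_p[r.SNP] = min(best_p.get(r.SNP, 1.0), float(r.P))

    # clump across the union using the best p per SNP
    union = sorted(best_p, key=lambda s: (best_p[s], s))
    kept = []
    for sid in union:
        independent = True
        if ld is not None:
            for other in kept:
                r2 = ld.r2(sid, other)
                if r2 is not None and r2 >= clump_r2:
                    independent = False
                    break
        if independent:
            kept.append(sid)

    out_by_snp = {r.SNP: r for r in outcome.table.itertuples()}
    exp_by_snp = [
        {r.SNP: r for r in e.table.itertuples()} for e in exposures
    ]
    rows, dropped = [], []
    for sid in kept:
        o = out_by_snp.get(sid)
        if o is None:
            dropped.append((sid, "missing_in_outcome"))
            continue
        ref_ea, ref_oa = o.EA, o.OA
        ref_eaf = float(o.EAF) if pd.notna(o.EAF) else np.nan
        row = {"snp_id": sid, "by": float(o.BETA), "se_y": float(o.SE)}
        ok = True
        for name, table in zip(names, exp_by_snp):
            r = table.get(sid)
            if r is None:
                dropped.append((sid, f"missing_in_{name}"))
                ok = False
                break
            beta, _, reason = align_record(
                ref_ea, ref_oa, ref_eaf, r.EA, r.OA, float(r.BETA),
                float(r.EAF) if pd.notna(r.EAF) else np.nan,
                palindrome_eaf_window,
            )
            if reason is not None:
                dropped.append((sid, f"{reason}_{name}"))
                ok = False
                break
            row[f"bx_{name}"] = beta
            row[f"se_{name}"] = float(r.SE)
        if ok:
            rows.append(row)

    K = len(names)
    if len(rows) < K + 1:
        raise UnderIdentifiedError(
            f"only {len(rows)} SNPs retained for {K} exposures (need >= {K + 1})"
        )
    cols = ["snp_id"]
    for name in names:
        cols += [f"bx_{name}", f"se_{name}"]
    cols += ["by", "se_y"]
    table = pd.DataFrame(rows)[cols]
    return MVHarmonisedSet(names, outcome.trait_name, table,
                           provenance=provenance, dropped=dropped,
                           outcome_scale=outcome.scale)


def _qa_weights(se_y, se_x, effects, corr=None):
    """Inverse of the per-SNP residual variance under the Q_A model."""
    effects = np.asarray(effects, float)
    var = se_y ** 2 + (se_x ** 2) @ (effects ** 2)
    K = se_x.shape[1]
    if corr is not None:
        for k in range(K):
            for l in range(k + 1, K):
                var = var + 2.0 * effects[k] * effects[l] * corr[k, l] \
                    * se_x[:, k] * se_x[:, l]
    with np.errstate(divide="ignore"):  # callers reject non-positive var
        w = 1.0 / var
    return w, var


def _corr_submatrix(pheno_corr, names):
    if pheno_corr is None:
        return None
    idx = [pheno_corr.trait_names.index(n) for n in names]
    return pheno_corr.matrix[np.ix_(idx, idx)]


def q_a(m: MVHarmonisedSet, effects, pheno_corr: PhenoCorrMatrix | None = None) -> HeterogeneityResult:
    """Q_A heterogeneity at a given effect vector.

    Q_A = sum_j w_j (by_j - sum_k beta_k bx_kj)^2 with
    w_j = 1 / (se_y^2 + sum_k beta_k^2 se_xk^2 + 2 sum_{k<l} beta_k beta_l
    cov(bx_k, bx_l)); the covariance uses the phenotypic correlation times
    the SE product and is zero when no matrix is supplied.  df = n - K.
    """
    effects = np.asarray(effects, float)
    if len(effects) != m.K:
        raise ValueError("effects length must equal number of exposures")
    corr = _corr_submatrix(pheno_corr, m.exposure_names)
    w, var = _qa_weights(m.se_y, m.se_x_matrix, effects, corr)
    if np.any(var <= 0):
        bad = m.table["snp_id"].to_numpy()[var <= 0]
        raise DegenerateWeightError(f"non-positive Q_A weight for SNPs {list(bad)}")
    resid = m.by - m.bx_matrix @ effects
    Q = float(np.sum(w * resid ** 2))
    df = m.n_snp - m.K
    pval = float(sps.chi2.sf(Q, df)) if df > 0 else np.nan
    return HeterogeneityResult(Q, df, pval)


def _check_rank(X, names):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the most collinear pair for the error message
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(X, rowvar=False)
        worst, pair = 0.0, tuple(names[:2])
        K = X.shape[1]
        for k in range(K):
            for l in range(k + 1, K):
                c = abs(C[k, l]) if np.isfinite(C[k, l]) else 1.0
                if c >= worst:
                    worst, pair = c, (names[k], names[l])
        raise CollinearityError(
            f"exposure beta matrix is rank deficient (most collinear: {pair[0]} vs {pair[1]})"
        )


def mvmr_ivw(m: MVHarmonisedSet, pheno_corr: PhenoCorrMatrix | None = None) -> MVMRResult:
    """IVW-MVMR: zero-intercept weighted least squares of by on the bx matrix.

    Weights are 1/se_y^2; SEs come from the weighted-regression covariance
    inflated by sqrt(max(1, Q_A/(n-K))) (multiplicative random effects),
    with Q_A evaluated at the fitted effects.
    """
    X = m.bx_matrix
    n, K = X.shape
    if n < K + 1:
        raise UnderIdentifiedError(f"{n} SNPs for {K} exposures")
    _check_rank(X, m.exposure_names)
    w = 1.0 / m.se_y ** 2
    xtwx = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(xtwx)
    beta = cov @ (X.T @ (w * m.by))
    het = q_a(m, beta, pheno_corr)
    infl = float(np.sqrt(max(1.0, het.Q / het.df))) if het.df > 0 else 1.0
    ses = np.sqrt(np.diag(cov)) * infl
    ests = [
        _estimate("mvmr_ivw", beta[k], ses[k], n, m.outcome_scale)
        for k in range(K)
    ]
    condf = conditional_f(m, pheno_corr) if n > K else None
    return MVMRResult(list(m.exposure_names), ests, het, condf)


def _minimise_q(fun, x0, what):
    # fatol scales with the objective so zero-SE (huge-Q) fixtures converge
    scale = max(1.0, abs(float(fun(np.asarray(x0, float)))))
    res = optimize.minimize(fun, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10 * scale,
                                     "maxiter": 5000})
    if not res.success:
        raise ConvergenceError(f"{what} minimisation did not converge", detail=res)
    return res


def conditional_f(m: MVHarmonisedSet, pheno_corr: PhenoCorrMatrix | None = None):
    """Per-exposure conditional F-statistics (instrument strength given the others).

    For exposure k the other exposures' betas are regressed on it by
    minimising the Q_A-form objective with trait k in the outcome role;
    F_k = Q_xk(min)/(n - K + 1).  K = 1 reports the univariable strength
    statistic mean(bx^2/se_x^2).
    """
    X = m.bx_matrix
    S = m.se_x_matrix
    n, K = X.shape
    if n <= K:
        raise UnderIdentifiedError("conditional F needs n_snp > K")
    if K == 1:
        s2 = np.maximum(S[:, 0] ** 2, 1e-12)  # zero SE = infinitely strong
        return np.array([float(np.mean(X[:, 0] ** 2 / s2))])
    corr = _corr_submatrix(pheno_corr, m.exposure_names)
    out = np.empty(K)
    for k in range(K):
        others = [l for l in range(K) if l != k]
        Xo = X[:, others]
        So = S[:, others]
        sy = S[:, k]
        corr_o = corr[np.ix_(others, others)] if corr is not None else None

        def qxk(delta):
            _, var = _qa_weights(sy, So, delta, corr_o)
            if np.any(var < 0):
                return np.inf
            # zero instrument SEs mean infinite precision; floor the variance
            # so the objective stays finite (F becomes astronomically large)
            var = np.maximum(var, 1e-12)
            resid = X[:, k] - Xo @ delta
            return float(np.sum(resid ** 2 / var))

        # start from the naive WLS fit with fixed weights 1/se_xk^2
        w0 = 1.0 / np.maximum(sy ** 2, 1e-12)
        xtwx = Xo.T @ (w0[:, None] * Xo)
        try:
            d0 = np.linalg.solve(xtwx, Xo.T @ (w0 * X[:, k]))
        except np.linalg.LinAlgError:
            d0 = np.zeros(K - 1)
        res = _minimise_q(qxk, d0, f"conditional F (exposure {m.exposure_names[k]})")
        out[k] = res.fun / (n - K + 1)
    return out


def pheno_corr_from_sumstats(traits, null_z_max: float = 2.0,
                             same_cohort: bool = True,
                             min_shared: int = 100) -> PhenoCorrMatrix:
    """Phenotypic correlation matrix from GWAS summary statistics.

    Entry (a, b) is the Pearson correlation of per-SNP z-scores (beta/se)
    over SNPs shared by both traits with |z| < ``null_z_max`` in both —
    at null SNPs the z-score correlation equals the phenotypic correlation
    when both GWAS come from the same cohort.  If ``same_cohort`` is False
    the identity matrix is returned (zero covariance between samples).
    The result is projected to the positive semi-definite cone if pairwise
    estimation leaves small negative eigenvalues.
    """
    traits = list(traits)
    names = [t.trait_name for t in traits]
    T = len(traits)
    if T < 2:
        raise ValueError("need >= 2 traits")
    if not same_cohort:
        return PhenoCorrMatrix.identity(names)
    zs = []
    for t in traits:
        tab = t.table
        z = pd.Series((tab["BETA"] / tab["SE"]).to_numpy(float),
                      index=tab["SNP"].to_numpy())
        zs.append(z)
    M = np.eye(T)
    n_used = None
    for i in range(T):
        for j in range(i + 1, T):
            shared = zs[i].index.intersection(zs[j].index)
            zi = zs[i].loc[shared]
            zj = zs[j].loc[shared]
            mask = (zi.abs() < null_z_max) & (zj.abs() < null_z_max)
            n_null = int(mask.sum())
            if n_null < min_shared:
                raise InsufficientDataError(
                    f"{names[i]} vs {names[j]}: only {n_null} shared null SNPs "
                    f"(need >= {min_shared})"
                )
            r = float(np.corrcoef(zi[mask], zj[mask])[0, 1])
            M[i, j] = M[j, i] = r
            n_used = n_null if n_used is None else min(n_used, n_null)
    # enforce positive semi-definiteness within tolerance
    evals, evecs = np.linalg.eigh(M)
    if evals.min() < -1e-8:
        evals = np.clip(evals, 0.0, None)
        M = evecs @ np.diag(evals) @ evecs.T
        d = np.sqrt(np.diag(M))
        M = M / np.outer(d, d)
    return PhenoCorrMatrix(names, M, n_used or 0)


def qhet_estimate(m: MVHarmonisedSet, pheno_corr: PhenoCorrMatrix | None = None,
                  n_boot: int = 500, seed: int = 0) -> MVMRResult:
    """Q-het: direct effects chosen to minimise Q_A, with bootstrap SEs.

    The minimisation starts at the IVW-MVMR solution (the objective is
    smooth and low dimensional); SEs come from a seeded nonparametric
    bootstrap over SNPs.
    """
    ivw_res = mvmr_ivw(m, pheno_corr)
    x0 = np.array([e.beta for e in ivw_res.estimates])

    def objective(beta, mset):
        try:
            return q_a(mset, beta, pheno_corr).Q
        except DegenerateWeightError:
            return np.inf

    res = _minimise_q(lambda b: objective(b, m), x0, "Q-het")
    beta_hat = np.asarray(res.x, float)
    rng = np.random.default_rng(seed)
    n = m.n_snp
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        mb = m.resample(idx)
        try:
            rb = optimize.minimize(lambda b: objective(b, mb), beta_hat,
                                   method="Nelder-Mead",
                                   options={"xatol": 1e-8, "fatol": 1e-8,
                                            "maxiter": 2000})
        except np.linalg.LinAlgError:
            continue
        if rb.success:
            boots.append(rb.x)
    if len(boots) >= 2:
        ses = np.std(np.asarray(boots), axis=0, ddof=1)
    else:
        ses = np.full(m.K, np.nan)
    het = q_a(m, beta_hat, pheno_corr)
    ests = [
        _estimate("qhet", beta_hat[k], ses[k], n, m.outcome_scale)
        for k in range(m.K)
    ]
    return MVMRResult(list(m.exposure_names), ests, het, ivw_res.conditional_f)
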