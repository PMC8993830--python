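"""Multivariable MR: estimator, Q_A, conditional F, phenotypic correlation, Q-het."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mrmediation.exceptions import (
    CollinearityError,
    DegenerateWeightError,
    InsufficientDataError,
    UnderIdentifiedError,
)
from mrmediation.mr import ivw
from mrmediation.mvmr import (
    MVHarmonisedSet,
    PhenoCorrMatrix,
    build_mv_set,
    conditional_f,
    mvmr_ivw,
    pheno_corr_from_sumstats,
    q_a,
    qhet_estimate,
)
from mrmediation.sumstats import HarmonisedSet, SummaryStats


def mvset(bx, by, se_y, se_x=None, **kw):
    return MVHarmonisedSet.from_arrays(bx, by, se_y, se_x=se_x, **kw)


EXACT_BX = [(1, 0), (0, 1), (1, 1)]
EXACT_BY = [0.2, 0.3, 0.5]


class TestMvmrIvw:
    def test_exact_fit_fixture(self):
        res = mvmr_ivw(mvset(EXACT_BX, EXACT_BY, [0.1, 0.1, 0.1]))
        assert res.estimates[0].beta == pytest.approx(0.2, abs=1e-12)
        assert res.estimates[1].beta == pytest.approx(0.3, abs=1e-12)
        assert res.q_a.Q == pytest.approx(0.0, abs=1e-12)

    def test_k1_equals_univariable_ivw(self, rng):
        bx = rng.normal(0.1, 0.05, 15)
        by = 0.3 * bx + rng.normal(0, 0.02, 15)
        se_y = rng.uniform(0.01, 0.05, 15)
        uni = ivw(HarmonisedSet.from_arrays(bx, by, se_y)).estimate.beta
        mv = mvmr_ivw(mvset(bx[:, None], by, se_y)).estimates[0].beta
        assert mv == pytest.approx(uni, abs=1e-10)

    def test_matches_wls_oracle(self, rng):
        X = rng.normal(0.1, 0.05, (30, 2))
        by = X @ [0.3, -0.2] + rng.normal(0, 0.02, 30)
        se_y = rng.uniform(0.01, 0.05, 30)
        fit = sm.WLS(by, X, weights=1 / se_y**2).fit()
        res = mvmr_ivw(mvset(X, by, se_y))
        assert res.estimates[0].beta == pytest.approx(fit.params[0], abs=1e-10)
        assert res.estimates[1].beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_collinearity_names_exposures(self, rng):
        x = rng.normal(0.1, 0.05, 10)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(CollinearityError, match="exposure"):
            mvmr_ivw(mvset(X, x, np.full(10, 0.02),
                           exposure_names=["bmi", "bmi_copy"]))

    def test_under_identified(self):
        with pytest.raises(UnderIdentifiedError):
            mvmr_ivw(mvset([(1, 0), (0, 1)], [0.1, 0.2], [0.1, 0.1]))


class TestQA:
    def test_zero_at_exact_fit(self):
        m = mvset(EXACT_BX, EXACT_BY, [0.1, 0.1, 0.1])
        assert q_a(m, [0.2, 0.3]).Q == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_cochran_q_in_limit(self, rng):
        bx = rng.normal(0.1, 0.05, 12)
        by = 0.3 * bx + rng.normal(0, 0.03, 12)
        se_y = rng.uniform(0.01, 0.05, 12)
        h = HarmonisedSet.from_arrays(bx, by, se_y)
        beta = ivw(h).estimate.beta
        q_uni = ivw(h).heterogeneity.Q
        qa = q_a(mvset(bx[:, None], by, se_y, se_x=np.zeros((12, 1))), [beta])
        assert qa.Q == pytest.approx(q_uni, abs=1e-10)
        assert qa.df == 11

    def test_hand_evaluated_sum_with_displacement(self):
        """One SNP's by displaced by +1; compare against an explicit loop."""
        bx = np.array(EXACT_BX, float)
        by = np.array([0.2, 0.3, 1.5])  # third displaced by +1
        se_y = np.array([0.1, 0.15, 0.2])
        se_x = np.array([[0.01, 0.02], [0.03, 0.01], [0.02, 0.02]])
        effects = [0.2, 0.3]
        expected = 0.0
        for j in range(3):
            var = se_y[j] ** 2
            for k in range(2):
                var += effects[k] ** 2 * se_x[j, k] ** 2
            resid = by[j] - sum(effects[k] * bx[j, k] for k in range(2))
            expected += resid ** 2 / var
        got = q_a(mvset(bx, by, se_y, se_x=se_x), effects)
        assert got.Q == pytest.approx(expected, abs=1e-12)
        assert got.df == 1

    def test_covariance_term_uses_pheno_corr(self):
        bx = np.array(EXACT_BX, float)
        se_x = np.full((3, 2), 0.1)
        corr = PhenoCorrMatrix(["exposure0", "exposure1"],
                               np.array([[1.0, 0.5], [0.5, 1.0]]))
        m = mvset(bx, [0.2, 0.3, 0.5], [0.1] * 3, se_x=se_x)
        effects = [0.2, 0.3]
        var = 0.1**2 + 0.2**2 * 0.01 + 0.3**2 * 0.01 + 2 * 0.2 * 0.3 * 0.5 * 0.01
        # exact fit: Q stays 0 regardless, so displace one by
        m2 = mvset(bx, [0.2, 0.3, 1.5], [0.1] * 3, se_x=se_x)
        got = q_a(m2, effects, corr)
        assert got.Q == pytest.approx(1.0**2 / var, abs=1e-12)

    def test_degenerate_weight_error(self):
        corr = PhenoCorrMatrix(["exposure0", "exposure1"],
                               np.array([[1.0, -1.0], [-1.0, 1.0]]))
        m = mvset([(1, 1)] * 3, [0.1] * 3, [0.0] * 3, se_x=np.full((3, 2), 1.0))
        with pytest.raises(DegenerateWeightError):
            q_a(m, [1.0, 1.0], corr)


class TestConditionalF:
    def test_k1_formula(self):
        m = mvset(np.array([[0.1], [0.1]]), [0.1, 0.1], [0.1, 0.1],
                  se_x=np.array([[0.01], [0.01]]))
        assert conditional_f(m)[0] == pytest.approx(100.0)

    def test_perfect_collinearity_gives_zero(self, rng):
        x = rng.normal(0.1, 0.05, 10)
        X = np.column_stack([x, x])
        m = mvset(X, 0.3 * x, np.full(10, 0.02), se_x=np.full((10, 2), 0.01))
        f = conditional_f(m)
        assert np.all(f < 1e-6)

    def test_rescaling_invariance(self, rng):
        X = rng.normal(0.1, 0.05, (20, 2))
        se_x = rng.uniform(0.005, 0.02, (20, 2))
        by = X @ [0.3, 0.1]
        m1 = mvset(X, by, np.full(20, 0.02), se_x=se_x)
        X2 = X.copy()
        X2[:, 1] *= 7.0
        se2 = se_x.copy()
        se2[:, 1] *= 7.0
        m2 = mvset(X2, by, np.full(20, 0.02), se_x=se2)
        f1 = conditional_f(m1)
        f2 = conditional_f(m2)
        assert f2 == pytest.approx(f1, rel=1e-6)

    def test_noise_exposure_flagged_weak(self):
        """An exposure whose instrument effects are pure noise has conditional F < 10."""
        rng = np.random.default_rng(11)
        weak = 0
        reps = 200
        for _ in range(reps):
            m_snp = 25
            bx1 = rng.normal(0, 0.1, m_snp)
            se = np.full((m_snp, 2), 0.01)
            bx2 = rng.normal(0, 0.01, m_snp)  # no true effects, only noise
            X = np.column_stack([bx1, bx2])
            by = 0.3 * bx1 + rng.normal(0, 0.02, m_snp)
            f = conditional_f(mvset(X, by, np.full(m_snp, 0.02), se_x=se))
            weak += f[1] < 10
        assert weak / reps >= 0.95


class TestPhenoCorr:
    def _stats(self, z, name):
        n = len(z)
        t = pd.DataFrame({
            "SNP": [f"rs{i}" for i in range(n)], "EA": "A", "OA": "G",
            "BETA": z, "SE": 1.0, "P": 0.5,
        })
        return SummaryStats(name, t)

    def test_self_correlation_is_one(self, rng):
        z = rng.normal(0, 1, 500)
        a = self._stats(z, "a")
        b = self._stats(z, "b")
        res = pheno_corr_from_sumstats([a, b])
        assert res.corr("a", "b") == pytest.approx(1.0)

    def test_different_cohorts_give_identity(self, rng):
        a = self._stats(rng.normal(0, 1, 500), "a")
        b = self._stats(rng.normal(0, 1, 500), "b")
        res = pheno_corr_from_sumstats([a, b], same_cohort=False)
        assert res.corr("a", "b") == 0.0

    def test_insufficient_shared_null_snps(self, rng):
        a = self._stats(rng.normal(0, 1, 50), "a")
        b = self._stats(rng.normal(0, 1, 50), "b")
        with pytest.raises(InsufficientDataError):
            pheno_corr_from_sumstats([a, b])

    def test_independent_null_traits_near_zero(self):
        """|r| < 3/sqrt(5000) in >= 95% of replicates for independent traits."""
        rng = np.random.default_rng(5)
        ok = 0
        reps = 100
        for _ in range(reps):
            a = self._stats(rng.normal(0, 1, 5000), "a")
            b = self._stats(rng.normal(0, 1, 5000), "b")
            r = pheno_corr_from_sumstats([a, b]).corr("a", "b")
            ok += abs(r) < 3 / np.sqrt(5000)
        assert ok / reps >= 0.95

    def test_shared_confounder_recovers_generative_correlation(self):
        """z-score correlation matches the truncated-bivariate-normal oracle."""
        rng = np.random.default_rng(17)
        rho = 0.25 / 1.25  # corr of two traits sharing a 0.5-loading confounder
        # oracle: expected correlation after |z| < 2 truncation in both margins
        zo = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 400_000)
        keep = (np.abs(zo[:, 0]) < 2) & (np.abs(zo[:, 1]) < 2)
        oracle = np.corrcoef(zo[keep, 0], zo[keep, 1])[0, 1]
        rs = []
        n, m = 4000, 2500
        for _ in range(10):
            G = (rng.random((n, m)) < 0.3) + (rng.random((n, m)) < 0.3)
            U = rng.normal(0, 1, n)
            x = 0.5 * U + rng.normal(0, 1, n)
            w = 0.5 * U + rng.normal(0, 1, n)
            from mrmediation.simulate import compute_association_stats
            a = compute_association_stats(x, G.astype(float), "quantitative",
                                          trait_name="a")
            b = compute_association_stats(w, G.astype(float), "quantitative",
                                          trait_name="b")
            rs.append(pheno_corr_from_sumstats([a, b]).corr("a", "b"))
        rs = np.asarray(rs)
        mc_se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean() - oracle) < 3 * mc_se + 0.005


class TestQhet:
    def test_exact_fit_matches_ivw(self):
        m = mvset(EXACT_BX, EXACT_BY, [0.1] * 3, se_x=np.full((3, 2), 0.05))
        res = qhet_estimate(m, n_boot=0)
        assert res.estimates[0].beta == pytest.approx(0.2, abs=1e-6)
        assert res.estimates[1].beta == pytest.approx(0.3, abs=1e-6)
        assert res.q_a.Q == pytest.approx(0.0, abs=1e-10)

    def test_zero_sex_limit_equals_ivw(self, rng):
        X = rng.normal(0.1, 0.05, (20, 2))
        by = X @ [0.3, -0.1] + rng.normal(0, 0.03, 20)
        se_y = rng.uniform(0.02, 0.05, 20)
        m = mvset(X, by, se_y, se_x=np.zeros((20, 2)))
        iv = mvmr_ivw(m)
        qh = qhet_estimate(m, n_boot=0)
        for a, b in zip(iv.estimates, qh.estimates):
            assert b.beta == pytest.approx(a.beta, abs=1e-6)

    def test_objective_not_worse_than_ivw(self, rng):
        X = rng.normal(0.1, 0.05, (25, 2))
        by = X @ [0.3, -0.1] + rng.normal(0, 0.05, 25)
        se_y = rng.uniform(0.02, 0.05, 25)
        m = mvset(X, by, se_y, se_x=rng.uniform(0.01, 0.03, (25, 2)))
        iv = mvmr_ivw(m)
        qh = qhet_estimate(m, n_boot=0)
        q_ivw = q_a(m, [e.beta for e in iv.estimates]).Q
        assert qh.q_a.Q <= q_ivw + 1e-10

    def test_agrees_with_ivw_without_pleiotropy(self):
        # strong-instrument regime: with appreciable instrument SEs Q-het
        # corrects part of the regression dilution that IVW carries, so the
        # two only coincide when that dilution is negligible
        rng = np.random.default_rng(23)
        diffs = []
        for _ in range(100):
            X_true = rng.normal(0, 0.1, (25, 2))
            se_x = np.full((25, 2), 0.0005)
            X = X_true + rng.normal(0, 0.0005, (25, 2))
            by = X_true @ [0.3, -0.1] + rng.normal(0, 0.02, 25)
            m = mvset(X, by, np.full(25, 0.02), se_x=se_x)
            iv = mvmr_ivw(m)
            qh = qhet_estimate(m, n_boot=0)
            diffs.append(qh.estimates[0].beta - iv.estimates[0].beta)
        diffs = np.asarray(diffs)
        mc_se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * mc_se + 1e-4

    def test_bootstrap_se_seeded(self, rng):
        X = rng.normal(0.1, 0.05, (15, 2))
        by = X @ [0.3, -0.1] + rng.normal(0, 0.03, 15)
        m = mvset(X, by, np.full(15, 0.03), se_x=np.full((15, 2), 0.01))
        a = qhet_estimate(m, n_boot=30, seed=4)
        b = qhet_estimate(m, n_boot=30, seed=4)
        assert a.estimates[0].se == b.estimates[0].se
        assert np.isfinite(a.estimates[0].se)


class TestBuildMvSet:
    def _trait(self, name, snps, betas, pvals, missing=(), ea="A", oa="G"):
        rows = []
        for s, b, p in zip(snps, betas, pvals):
            if s in missing:
                continue
            rows.append({"SNP": s, "CHR": "1", "POS": 1, "EA": ea, "OA": oa,
                         "EAF": 0.3, "BETA": b, "SE": 0.01, "P": p, "N": 1000})
        return SummaryStats(name, pd.DataFrame(rows))

    def test_union_and_dedup(self):
        snps = [f"rs{i}" for i in range(12)]
        p1 = [1e-10] * 5 + [0.5] * 7
        p2 = [0.5] * 4 + [1e-10] * 5 + [0.5] * 3  # rs4 selected by both
        e1 = self._trait("e1", snps, [0.1] * 12, p1)
        e2 = self._trait("e2", snps, [0.1] * 12, p2)
        out = self._trait("out", snps, [0.05] * 12, [0.5] * 12)
        m = build_mv_set([e1, e2], out)
        assert m.n_snp == 9  # 5 + 5 with one shared
        assert sorted(m.provenance["rs4"]) == ["e1", "e2"]

    def test_missing_in_outcome_dropped_with_reason(self):
        snps = [f"rs{i}" for i in range(6)]
        e1 = self._trait("e1", snps, [0.1] * 6, [1e-10] * 6)
        e2 = self._trait("e2", snps, [0.1] * 6, [1e-9] * 6)
        out = self._trait("out", snps, [0.05] * 6, [0.5] * 6, missing=("rs2",))
        m = build_mv_set([e1, e2], out)
        assert ("rs2", "missing_in_outcome") in m.dropped
        assert m.n_snp == 5

    def test_under_identified_error(self):
        snps = ["rs0", "rs1"]
        e1 = self._trait("e1", snps, [0.1, 0.1], [1e-10, 1e-9])
        e2 = self._trait("e2", snps, [0.1, 0.1], [1e-10, 1e-9])
        out = self._trait("out", snps, [0.05, 0.05], [0.5, 0.5])
        with pytest.raises(UnderIdentifiedError):
            build_mv_set([e1, e2], out)

    def test_alignment_to_outcome_frame(self):
        snps = ["rs0", "rs1", "rs2", "rs3"]
        e1 = self._trait("e1", snps, [0.1, 0.2, 0.3, 0.4], [1e-10] * 4)
        e2 = self._trait("e2", snps, [0.1] * 4, [1e-9] * 4)
        out = self._trait("out", snps, [0.05] * 4, [0.5] * 4, ea="G", oa="A")
        m = build_mv_set([e1, e2], out)
        # exposure betas flipped into the outcome's (swapped) frame
        assert m.table["bx_e1"].tolist() == pytest.approx([-0.1, -0.2, -0.3, -0.4])


def test_noise_exposure_leaves_first_estimate_unbiased():
    """Adding a pure-noise exposure leaves the first direct effect near its K=1 value."""
    rng = np.random.default_rng(31)
    deltas = []
    for _ in range(200):
        m_snp = 25
        bx1_true = rng.normal(0, 0.1, m_snp)
        bx1 = bx1_true + rng.normal(0, 0.01, m_snp)
        bx2 = rng.normal(0, 0.01, m_snp)
        by = 0.3 * bx1_true + rng.normal(0, 0.02, m_snp)
        se_y = np.full(m_snp, 0.02)
        k1 = ivw(HarmonisedSet.from_arrays(bx1, by, se_y)).estimate.beta
        k2 = mvmr_ivw(mvset(np.column_stack([bx1, bx2]), by, se_y,
                            se_x=np.full((m_snp, 2), 0.01))).estimates[0].beta
        deltas.append(k2 - k1)
    deltas = np.asarray(deltas)
    mc_se = deltas.std(ddof=1) / np.sqrt(len(deltas))
    assert abs(deltas.mean()) < 3 * mc_se + 1e-4
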