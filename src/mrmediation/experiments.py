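"""Replicated experiments under the generator's study conditions.

Each experiment composes the synthetic-data generator with the estimators
and returns summary dictionaries: null calibration of the IVW test,
parameter recovery for the product-method indirect effect, the
winner's-curse contrast between fully overlapping and split-sample
designs, and the product-vs-difference comparison under a common binary
outcome.  All randomness flows from one integer seed through
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np

from .mediation import MediationInputs, difference_method, product_method
from .mr import ivw
from .mvmr import build_mv_set, mvmr_ivw
from .simulate import (
    SimConfig,
    calibrate_b0,
    compute_association_stats,
    default_snp_meta,
    draw_effects,
    rank_inverse_normal,
    simulate_study_fast,
    _genotypes_given_mafs,
    _gs_dot,
    _noise_sd,
    _rng,
)
from .sumstats import harmonise, select_instruments


def _child_seeds(seed: int, n: int):
    return [int(s) % 2**31 for s in np.random.SeedSequence(seed).generate_state(n)]


def null_calibration(n_reps: int = 1000, seed: int = 0, alpha: float = 0.05,
                     n: int = 20_000, m: int = 150) -> dict:
    """Type-I error of the IVW test with valid instruments and no causal effect.

    Disjoint exposure/outcome cohorts, a common binary outcome, and the
    default genome-wide selection threshold; the exposure keeps its
    genetic architecture so instruments exist, but every causal,
    pleiotropic and confounding path to the outcome is zero.
    """
    rejections = 0
    used = 0
    for s in _child_seeds(seed, n_reps):
        cfg = SimConfig(n=n, m_exposure=m, m_mediator=0, theta=0.0, tau=0.0,
                        delta=0.0, c_x=0.0, c_z=0.0, c_y=0.0, seed=s)
        fs = simulate_study_fast(cfg, with_mediator=False)
        inst = select_instruments(fs.exposure)
        if len(inst) == 0:
            continue
        res = ivw(harmonise(inst, fs.outcome))
        used += 1
        rejections += res.estimate.pval < alpha
    return {"rejection_rate": rejections / used, "n_reps": used, "alpha": alpha}


def recovery_experiment(n_reps: int = 500, seed: int = 0,
                        config: SimConfig | None = None) -> dict:
    """Product-method recovery of theta*tau and IVW coverage of the total effect.

    Runs the default scenario's continuous-outcome variant (the
    collapsible case, where the true indirect effect is exactly
    theta*tau) over disjoint cohorts: per replicate, step 1 IVW
    (exposure -> mediator) times the MVMR mediator direct effect gives
    the product-method indirect estimate.
    """
    base = config or SimConfig(outcome_type="continuous")
    indirect = []
    truth_ind = base.theta * base.tau
    for s in _child_seeds(seed, n_reps):
        cfg = SimConfig(**{**base.__dict__, "seed": s, "outcome_type": "continuous"})
        fs = simulate_study_fast(cfg)
        inst = select_instruments(fs.exposure)
        step1 = ivw(harmonise(inst, fs.mediator))
        mset = build_mv_set([fs.exposure, fs.mediator], fs.outcome)
        tau_hat = mvmr_ivw(mset).estimate_for("mediator")
        indirect.append(step1.estimate.beta * tau_hat.beta)
    indirect = np.asarray(indirect)
    return {
        "indirect_mean": float(indirect.mean()),
        "indirect_mc_se": float(indirect.std(ddof=1) / np.sqrt(len(indirect))),
        "true_indirect": truth_ind,
        "n_reps": n_reps,
    }


def coverage_experiment(n_reps: int = 500, seed: int = 0,
                        config: SimConfig | None = None) -> dict:
    """IVW 95% CI coverage of the true total effect, binary outcome.

    Half the replicates run the default scenario (true total = the
    marginal do-intervention log-odds contrast, computed once on a
    200k-individual pilot and shared across replicates), half run the
    global null (true total = 0).  The binary outcome reproduces the
    case-control noise regime in which the method operates: outcome-side
    SEs dominate the CI, as in a real consortium GWAS.
    """
    base = config or SimConfig()
    n_nonnull = n_reps // 2
    seeds = _child_seeds(seed, n_reps + 1)
    eff0 = draw_effects(base, seeds[-1])
    b0, truth_total = calibrate_b0(base, eff0, seeds[-1])
    covered = 0
    for i, s in enumerate(seeds[:n_reps]):
        if i < n_nonnull:
            cfg = SimConfig(**{**base.__dict__, "seed": s, "b0": b0})
            truth = truth_total
        else:
            cfg = SimConfig(n=base.n, m_exposure=base.m_exposure, m_mediator=0,
                            theta=0.0, tau=0.0, delta=0.0, c_x=0.0, c_z=0.0,
                            c_y=0.0, seed=s)
            truth = 0.0
        fs = simulate_study_fast(cfg, with_mediator=False)
        est = ivw(harmonise(select_instruments(fs.exposure), fs.outcome)).estimate
        covered += est.ci_low <= truth <= est.ci_high
    return {"coverage": covered / n_reps, "true_total_nonnull": truth_total,
            "n_reps": n_reps}


def winners_curse_experiment(n_reps: int = 200, seed: int = 0,
                             n: int = 20_000, m: int = 150,
                             h2_exposure: float = 0.2) -> dict:
    """Selection-induced exposure-beta inflation: full overlap vs split sample.

    Each replicate draws one cohort.  Fully-overlapping design: instruments
    are selected from, and their betas taken from, the full-cohort exposure
    GWAS — the sample that also hosts the downstream GWAS.  Split design:
    instruments are selected from a half-A GWAS and their effects
    re-estimated in half B, the half feeding the downstream GWAS, so the
    selection is decoupled from the betas in play.  Inflation per replicate
    is the mean signed excess of the estimated over the generative
    per-allele effect across selected SNPs.  A deliberately modest
    heritability makes the 5e-8 threshold binding.
    """
    cfg_proto = SimConfig(n=n, m_exposure=m, m_mediator=0, h2_exposure=h2_exposure,
                          theta=0.0, tau=0.0, delta=0.0, c_y=0.0)
    overlap_infl, split_infl = [], []
    for s in _child_seeds(seed, n_reps):
        ss = np.random.SeedSequence(s)
        k_eff, k_maf, k_g, k_p = ss.spawn(4)
        effects = draw_effects(cfg_proto, k_eff)
        mafs = _rng(k_maf).uniform(*cfg_proto.maf_range, effects.m_total)
        alpha_allele = effects.alpha / np.sqrt(2 * mafs * (1 - mafs))
        G = _genotypes_given_mafs(_rng(k_g), n, mafs)
        rng = _rng(k_p)
        U = rng.normal(0.0, 1.0, n)
        var_gx = float(np.sum(effects.alpha ** 2))
        X = _gs_dot(G, mafs, effects.alpha) + cfg_proto.c_x * U \
            + rng.normal(0.0, _noise_sd(var_gx + cfg_proto.c_x ** 2), n)
        X = (X - X.mean()) / X.std()
        meta = default_snp_meta(effects.m_total, seed=0)

        def excess(stats, sel_ids):
            idx = [int(sid[2:]) - 1 for sid in sel_ids]
            tab = stats.table.set_index("SNP")
            bhat = tab.loc[sel_ids, "BETA"].to_numpy(float)
            a = alpha_allele[idx]
            return float(np.mean((bhat - a) * np.sign(a)))

        # fully overlapping: selection and betas from the same full-cohort GWAS
        full = compute_association_stats(rank_inverse_normal(X), G, "quantitative",
                                         None, meta, trait_name="exposure")
        sel_full = select_instruments(full)
        # split: discovery in half A, effects re-estimated in half B
        half = n // 2
        a_idx, b_idx = np.arange(half), np.arange(half, n)
        half_a = compute_association_stats(rank_inverse_normal(X[a_idx]), G[a_idx],
                                           "quantitative", None, meta,
                                           trait_name="exposure_a")
        sel_a = select_instruments(half_a)
        if len(sel_full) == 0 or len(sel_a) == 0:
            continue
        cols = [int(sid[2:]) - 1 for sid in sel_a.table["SNP"]]
        half_b = compute_association_stats(
            rank_inverse_normal(X[b_idx]), G[np.ix_(b_idx, cols)], "quantitative",
            None, meta.iloc[cols].reset_index(drop=True), trait_name="exposure_b")
        overlap_infl.append(excess(full, list(sel_full.table["SNP"])))
        split_infl.append(excess(half_b, list(half_b.table["SNP"])))
    return {
        "overlap_inflation": np.asarray(overlap_infl),
        "split_inflation": np.asarray(split_infl),
        "n_reps": len(overlap_infl),
    }


def mediation_method_comparison(n_reps: int = 200, seed: int = 0,
                                config: SimConfig | None = None) -> dict:
    """Product vs difference decompositions under a common binary outcome.

    Uses a strong-mediation scenario (default theta=0.5, tau=0.7,
    delta=-0.5, 53.7% cases) where the non-collapsibility of the odds
    ratio is resolvable at feasible replicate counts.  The baseline
    log-odds is calibrated once on a pilot draw and reused across
    replicates (its variation across effect re-draws is negligible).
    Returns per-replicate product and difference indirect estimates.
    """
    base = config or SimConfig(theta=0.5, tau=0.7, delta=-0.5)
    seeds = _child_seeds(seed, n_reps + 1)
    eff0 = draw_effects(base, seeds[-1])
    b0, _ = calibrate_b0(base, eff0, seeds[-1], n_pilot=100_000)
    product, difference = [], []
    for s in seeds[:n_reps]:
        cfg = SimConfig(**{**base.__dict__, "seed": s, "b0": b0})
        fs = simulate_study_fast(cfg)
        inst = select_instruments(fs.exposure)
        step1 = ivw(harmonise(inst, fs.mediator)).estimate
        total = ivw(harmonise(inst, fs.outcome)).estimate
        mset = build_mv_set([fs.exposure, fs.mediator], fs.outcome)
        mv = mvmr_ivw(mset)
        inputs = MediationInputs(total=total, step1=step1,
                                 mediator_direct=mv.estimate_for("mediator"),
                                 exposure_direct=mv.estimate_for("exposure"))
        product.append(product_method(inputs).indirect)
        difference.append(difference_method(inputs).indirect)
    return {
        "product": np.asarray(product),
        "difference": np.asarray(difference),
        "true_indirect_conditional": base.theta * base.tau,
        "n_reps": n_reps,
    }
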