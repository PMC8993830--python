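"""Config-driven mediator-prioritisation pipeline.

Screens candidate mediators of an exposure -> outcome effect in stages:

1. two-step MR per mediator (exposure->mediator, mediator->outcome), each
   with the full sensitivity battery;
2. mediators with evidence in at least one step *and* consistent
   sensitivity results in both proceed to MVMR (exposure + mediator
   jointly on the outcome);
3. mediators with MVMR evidence for a direct effect and conditional
   F > 10 for both exposures proceed to mediation (product and difference
   decompositions).

"Evidence" is operationalised as the 95% CI excluding the null;
"consistency" as sign agreement between IVW and the pleiotropy-robust
estimators.  All thresholds are configurable and echoed into each
decision record, and decisions are pure functions of estimates plus
thresholds.  Per-mediator hard errors are recorded and the pipeline
continues for the remaining mediators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import MRError
from .mediation import (
    MediationInputs,
    MediationResult,
    difference_method,
    product_method,
    run_two_step,
)
from .mr import MREstimate, MRReport, univariable_battery
from .mvmr import CONDITIONAL_F_THRESHOLD, MVMRResult, build_mv_set, mvmr_ivw
from .sumstats import (
    CLUMP_R2,
    GWAS_P_THRESHOLD,
    harmonise,
    read_summary_stats,
    select_instruments,
)


@dataclass
class EvidenceRules:
    """Thresholds behind the prioritisation verdicts."""

    egger_intercept_threshold: float = 0.002
    q_pval_threshold: float = 0.05
    conditional_f_threshold: float = CONDITIONAL_F_THRESHOLD


@dataclass
class Verdict:
    """Outcome of evaluating one MR report against the evidence rules."""

    evidence: bool
    consistency: bool
    pleiotropy: bool
    details: dict = field(default_factory=dict)


def evaluate_evidence(report: MRReport, rules: EvidenceRules | None = None) -> Verdict:
    """Judge one univariable MR report.

    evidence: the IVW 95% CI excludes the null.  consistency: the
    weighted-median (and Egger slope, when computable) point estimates
    agree in sign with IVW.  pleiotropy: |Egger intercept| at or above the
    threshold, or Cochran's Q p below its threshold.
    """
    rules = rules or EvidenceRules()
    est = report.ivw
    evidence = est.ci_excludes_null()
    consistency = True
    if report.weighted_median is not None:
        consistency &= np.sign(report.weighted_median.beta) == np.sign(est.beta)
    if report.egger is not None:
        consistency &= np.sign(report.egger.slope.beta) == np.sign(est.beta)
    pleiotropy = False
    if report.egger is not None:
        pleiotropy |= abs(report.egger.intercept.beta) >= rules.egger_intercept_threshold
    if report.heterogeneity is not None and np.isfinite(report.heterogeneity.pval):
        pleiotropy |= report.heterogeneity.pval < rules.q_pval_threshold
    details = {
        "ivw_beta": est.beta, "ivw_ci": (est.ci_low, est.ci_high),
        "n_snp": est.n_snp,
        "egger_intercept": report.egger.intercept.beta if report.egger else None,
        "egger_intercept_threshold": rules.egger_intercept_threshold,
        "q_pval": report.heterogeneity.pval if report.heterogeneity else None,
        "q_pval_threshold": rules.q_pval_threshold,
    }
    return Verdict(bool(evidence), bool(consistency), bool(pleiotropy), details)


@dataclass
class PrioritisationDecision:
    mediator: str
    stage_reached: str  # "two_step", "mvmr" or "mediation"
    verdicts: dict = field(default_factory=dict)
    reasons: list = field(default_factory=list)
    error: str | None = None


def prioritise_mediators(two_step_verdicts: dict, mvmr_info: dict | None = None,
                         rules: EvidenceRules | None = None):
    """Apply the staged selection rules.

    ``two_step_verdicts`` maps mediator -> (step1 Verdict, step2 Verdict);
    ``mvmr_info`` maps mediator -> dict with keys ``mediator_evidence``
    (bool, MVMR direct-effect CI excludes null) and ``conditional_f``
    (sequence of per-exposure F).  A mediator reaches "mvmr" with
    evidence in >= 1 step and consistency in both; it reaches "mediation"
    with, additionally, MVMR evidence and all conditional F above the
    threshold.  Output order follows sorted mediator names (decisions are
    order-independent).
    """
    rules = rules or EvidenceRules()
    mvmr_info = mvmr_info or {}
    decisions = []
    for name in sorted(two_step_verdicts):
        v1, v2 = two_step_verdicts[name]
        reasons = []
        verdicts = {"step1": v1, "step2": v2}
        if not (v1.evidence or v2.evidence):
            reasons.append("no evidence in either two-step MR step")
        if not (v1.consistency and v2.consistency):
            reasons.append("inconsistent sensitivity estimates in two-step MR")
        if reasons:
            decisions.append(PrioritisationDecision(name, "two_step", verdicts, reasons))
            continue
        info = mvmr_info.get(name)
        if info is None:
            decisions.append(PrioritisationDecision(
                name, "mvmr", verdicts, ["MVMR results unavailable"]))
            continue
        verdicts["mvmr"] = info
        if not info.get("mediator_evidence", False):
            reasons.append("no evidence of a direct mediator effect in MVMR")
        condf = np.asarray(info.get("conditional_f", []), float)
        if condf.size == 0 or np.any(condf <= rules.conditional_f_threshold):
            reasons.append(
                f"conditional F not above {rules.conditional_f_threshold} for all exposures"
            )
        stage = "mvmr" if reasons else "mediation"
        decisions.append(PrioritisationDecision(name, stage, verdicts, reasons))
    return decisions


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters for a full pipeline run."""

    exposure: str
    outcome: str
    mediators: dict  # name -> path
    out_dir: str = "pipeline_out"
    outcome_binary: bool = True
    p_threshold: float = GWAS_P_THRESHOLD
    clump_r2: float = CLUMP_R2
    ivw_model: str = "random"
    n_boot: int = 1000
    seed: int = 0
    rules: EvidenceRules = field(default_factory=EvidenceRules)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        rules = EvidenceRules(**raw.pop("rules", {}))
        cfg = cls(rules=rules, **raw)
        for p in [cfg.exposure, cfg.outcome, *cfg.mediators.values()]:
            if not Path(p).exists():
                raise FileNotFoundError(f"summary-statistics file not found: {p}")
        if not 0 < cfg.p_threshold < 1:
            raise ValueError("p_threshold out of range")
        if not 0 <= cfg.clump_r2 <= 1:
            raise ValueError("clump_r2 out of range")
        return cfg


def _estimate_row(exposure, outcome, est: MREstimate) -> dict:
    row = {
        "exposure": exposure, "outcome": outcome, "method": est.method,
        "nsnp": est.n_snp, "beta": est.beta, "se": est.se,
        "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval,
        "scale": est.scale,
    }
    if est.scale == "log_odds":
        row["or"] = float(np.exp(est.beta))
        row["or_ci_low"] = float(np.exp(est.ci_low))
        row["or_ci_high"] = float(np.exp(est.ci_high))
    return row


def mr_report_table(report: MRReport) -> pd.DataFrame:
    """Serialise one univariable battery to the tab-separated layout."""
    rows = [_estimate_row(report.exposure_name, report.outcome_name, report.ivw)]
    if report.egger is not None:
        rows.append(_estimate_row(report.exposure_name, report.outcome_name,
                                  report.egger.slope))
        rows.append(_estimate_row(report.exposure_name, report.outcome_name,
                                  report.egger.intercept))
    if report.weighted_median is not None:
        rows.append(_estimate_row(report.exposure_name, report.outcome_name,
                                  report.weighted_median))
    df = pd.DataFrame(rows)
    if report.heterogeneity is not None:
        df["Q"] = report.heterogeneity.Q
        df["Q_df"] = report.heterogeneity.df
        df["Q_pval"] = report.heterogeneity.pval
    return df


def mvmr_result_table(res: MVMRResult) -> pd.DataFrame:
    rows = []
    for k, name in enumerate(res.exposure_names):
        est = res.estimates[k]
        rows.append({
            "exposure": name, "nsnp": est.n_snp, "beta": est.beta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high, "pval": est.pval,
            "cond_F": float(res.conditional_f[k]) if res.conditional_f is not None else np.nan,
            "Q_A": res.q_a.Q if res.q_a else np.nan,
            "Q_A_df": res.q_a.df if res.q_a else np.nan,
            "Q_A_p": res.q_a.pval if res.q_a else np.nan,
        })
    return pd.DataFrame(rows)


def mediation_result_row(exposure, mediator, outcome, res: MediationResult) -> dict:
    prop = res.proportion_mediated
    return {
        "exposure": exposure, "mediator": mediator, "outcome": outcome,
        "method": res.method, "indirect": res.indirect, "se": res.se,
        "ci_low": res.ci_low, "ci_high": res.ci_high,
        "proportion_mediated": prop.value if prop else np.nan,
        "flags": ";".join(res.flags + (prop.flags if prop else [])) or "-",
    }


@dataclass
class PipelineResult:
    total: MRReport
    two_step: dict
    mvmr: dict
    mediation: list
    decisions: list
    out_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute select -> harmonise -> two-step -> prioritise -> MVMR -> mediation.

    Writes all stage tables, the decision table and a run manifest into
    ``config.out_dir``.  Hard errors for one mediator are recorded in its
    decision and the pipeline continues for the others.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out_type = "binary" if config.outcome_binary else "quantitative"
    exposure = read_summary_stats(config.exposure, trait_name="exposure")
    outcome = read_summary_stats(config.outcome, trait_name="outcome",
                                 trait_type=out_type)
    mediators = {
        name: read_summary_stats(path, trait_name=name)
        for name, path in config.mediators.items()
    }

    exp_inst = select_instruments(exposure, config.p_threshold, config.clump_r2)
    total_report = univariable_battery(
        harmonise(exp_inst, outcome), model=config.ivw_model,
        n_boot=config.n_boot, seed=config.seed,
    )

    two_step, verdicts, errors = {}, {}, {}
    for name, med in sorted(mediators.items()):
        try:
            ts = run_two_step(exposure, med, outcome,
                              p_threshold=config.p_threshold,
                              clump_r2=config.clump_r2, model=config.ivw_model,
                              n_boot=config.n_boot, seed=config.seed)
            two_step[name] = ts
            verdicts[name] = (evaluate_evidence(ts.step1, config.rules),
                              evaluate_evidence(ts.step2, config.rules))
        except MRError as exc:
            errors[name] = f"two_step: {exc}"

    stage1 = prioritise_mediators(verdicts, None, config.rules)
    candidates = [d.mediator for d in stage1 if d.stage_reached != "two_step"]

    mvmr_results, mvmr_info = {}, {}
    for name in candidates:
        try:
            mset = build_mv_set([exposure, mediators[name]], outcome,
                                p_threshold=config.p_threshold,
                                clump_r2=config.clump_r2)
            res = mvmr_ivw(mset)
            mvmr_results[name] = res
            mvmr_info[name] = {
                "mediator_evidence": res.estimate_for(name).ci_excludes_null(),
                "conditional_f": res.conditional_f,
            }
        except MRError as exc:
            errors[name] = f"mvmr: {exc}"

    decisions = prioritise_mediators(verdicts, mvmr_info, config.rules)
    for d in decisions:
        if d.mediator in errors:
            d.error = errors[d.mediator]
    decided = {d.mediator for d in decisions}
    for name in sorted(set(errors) - decided):
        decisions.append(PrioritisationDecision(
            name, "two_step", {}, ["hard error during analysis"],
            error=errors[name]))
    decisions.sort(key=lambda d: d.mediator)

    mediation_rows, mediation_results = [], []
    for d in decisions:
        if d.stage_reached != "mediation":
            continue
        name = d.mediator
        res = mvmr_results[name]
        inputs = MediationInputs(
            total=total_report.ivw,
            step1=two_step[name].step1.ivw,
            mediator_direct=res.estimate_for(name),
            exposure_direct=res.estimate_for("exposure"),
        )
        for method in (product_method, difference_method):
            mres = method(inputs)
            mediation_results.append((name, mres))
            mediation_rows.append(
                mediation_result_row("exposure", name, "outcome", mres))

    # ---- write the report bundle -------------------------------------
    mr_report_table(total_report).to_csv(out_dir / "total_effect.tsv",
                                         sep="\t", index=False, na_rep="NA")
    ts_tables = []
    for name, ts in sorted(two_step.items()):
        t1 = mr_report_table(ts.step1)
        t1.insert(0, "step", "step1")
        t2 = mr_report_table(ts.step2)
        t2.insert(0, "step", "step2")
        t = pd.concat([t1, t2], ignore_index=True)
        t.insert(0, "mediator", name)
        ts_tables.append(t)
    if ts_tables:
        pd.concat(ts_tables, ignore_index=True).to_csv(
            out_dir / "two_step.tsv", sep="\t", index=False, na_rep="NA")
    mv_tables = []
    for name, res in sorted(mvmr_results.items()):
        t = mvmr_result_table(res)
        t.insert(0, "mediator", name)
        mv_tables.append(t)
    if mv_tables:
        pd.concat(mv_tables, ignore_index=True).to_csv(
            out_dir / "mvmr.tsv", sep="\t", index=False, na_rep="NA")
    if mediation_rows:
        pd.DataFrame(mediation_rows).to_csv(
            out_dir / "mediation.tsv", sep="\t", index=False, na_rep="NA")
    dec_rows = [{
        "mediator": d.mediator, "stage_reached": d.stage_reached,
        "reasons": "; ".join(d.reasons) or "-", "error": d.error or "-",
    } for d in decisions]
    pd.DataFrame(dec_rows).to_csv(out_dir / "decisions.tsv", sep="\t",
                                  index=False, na_rep="NA")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "p_threshold": config.p_threshold,
        "clump_r2": config.clump_r2,
        "ivw_model": config.ivw_model,
        "n_boot": config.n_boot,
        "outcome_binary": config.outcome_binary,
        "rules": {
            "egger_intercept_threshold": config.rules.egger_intercept_threshold,
            "q_pval_threshold": config.rules.q_pval_threshold,
            "conditional_f_threshold": config.rules.conditional_f_threshold,
        },
        "inputs": {"exposure": str(config.exposure), "outcome": str(config.outcome),
                   "mediators": {k: str(v) for k, v in config.mediators.items()}},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return PipelineResult(total_report, two_step, mvmr_results,
                          mediation_results, decisions, out_dir)
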