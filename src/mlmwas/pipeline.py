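"""End-to-end orchestration on synthetic cohort pairs.

Reproduces the analysis shape of a two-cohort methylation case-control
study: simulate discovery/target cohorts, probe QC, cell-type deconvolution,
covariate residualization, relationship matrix, OREML variance-component
models, four MWAS engines, BLUP and thresholded profile scores carried into
the target cohort, classification, and cross-cohort effect-size
correlation.  Every stage logs probe/individual counts and all report
numbers trace to stage output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import mwas as mw
from . import preprocess as pp
from . import scoring as sc
from .io import write_methylation, write_mwas
from .orm import compute_orm
from .reml import ctp_fixed_effects, reml_fit
from .sim import SimConfig, simulate_cohort_pair

DEFAULT_P_GRID = (1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)

CONFOUNDER_COVARIATES = ["age", "sex", "smoking_score", "batch",
                         "chip_position"]


@dataclass
class PipelineConfig:
    """Single configuration object for a full synthetic-pair run."""

    sim: SimConfig = field(default_factory=SimConfig)
    moment: mw.MomentConfig = field(default_factory=mw.MomentConfig)
    p_thresholds: tuple = DEFAULT_P_GRID
    pc_k: int = 10
    run_moment: bool = True
    ctp_drop: str | None = None  # compositional reference cell type

    def __post_init__(self) -> None:
        self.p_thresholds = tuple(sorted(self.p_thresholds))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.get("sim", {}))
        moment = mw.MomentConfig(**raw.get("moment", {}))
        kwargs = {
            k: v for k, v in raw.items() if k not in ("sim", "moment")
        }
        return cls(sim=sim, moment=moment, **kwargs)


def _residualize_for_mwas(M_beta, samples, ctp, drop):
    """Filtered + CTP/covariate-residualized + restandardized matrix."""
    ctp_cols = [c for c in ctp.columns if c != drop]
    S = samples.copy()
    for c in ctp_cols:
        S[f"ctp_{c}"] = ctp[c].to_numpy()
    covs = CONFOUNDER_COVARIATES + [f"ctp_{c}" for c in ctp_cols]
    return pp.residualize(pp.standardize(M_beta), S, covs)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a simulated cohort pair; returns the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {"seed": config.sim.seed,
                               "m_probes": config.sim.m_probes}}

    disc, tgt = simulate_cohort_pair(config.sim)
    write_methylation(
        disc.methylation, disc.samples,
        outdir / "discovery_beta.tsv", outdir / "discovery_probes.opi",
        outdir / "discovery_samples.tsv",
    )
    report["simulate"] = {
        "discovery_n": disc.methylation.n_samples,
        "discovery_m": disc.methylation.n_probes,
        "target_n": tgt.methylation.n_samples,
        "target_m": tgt.methylation.n_probes,
    }

    # --- QC
    discM, disc_qc = pp.filter_probes(disc.methylation)
    tgtM, tgt_qc = pp.filter_probes(tgt.methylation)
    report["qc"] = {
        "discovery": dataclasses.asdict(disc_qc),
        "target": dataclasses.asdict(tgt_qc),
    }

    # --- cell-type proportions
    ctp_d = pp.estimate_ctp(discM, disc.reference)
    ctp_t = pp.estimate_ctp(tgtM, tgt.reference)
    ctp_d.to_csv(outdir / "discovery_ctp.tsv", sep="\t", index=False)
    drop = config.ctp_drop or ctp_d.columns[-1]
    ctp_assoc = ev.stepwise_ctp_logistic(
        ctp_d * 100.0, disc.samples["status"].to_numpy()
    )
    ctp_assoc.to_csv(outdir / "ctp_stepwise.tsv", sep="\t", index=False)
    report["ctp"] = {
        "retained_cell_types": ctp_assoc["cell_type"].tolist(),
    }

    # --- residualized matrix for MWAS
    Wres = _residualize_for_mwas(discM, disc.samples, ctp_d, drop)

    # --- ORM + OREML covariate ladder
    Wstd = pp.standardize(discM)
    A = compute_orm(Wstd)
    y = disc.samples["status"].to_numpy(float)
    conf = pp.design_from_covariates(
        disc.samples, CONFOUNDER_COVARIATES
    )[:, 1:]
    ctp_cols = [c for c in ctp_d.columns if c != drop]
    ctp_mat = ctp_d.loc[:, ctp_cols].to_numpy(float)
    models = {
        "no_covariates": None,
        "confounders": conf,
        "ctp": ctp_mat,
        "confounders_ctp": np.column_stack([conf, ctp_mat]),
    }
    oreml_rows = []
    for label, Cmat in models.items():
        fit = reml_fit(y, Cmat, [A])
        oreml_rows.append(
            {"model": label, "rho2": fit.rho2, "se_rho2": fit.se_rho2,
             "sigma_P2": fit.sigma_P2, "converged": fit.converged}
        )
    oreml_df = pd.DataFrame(oreml_rows)
    oreml_df.to_csv(outdir / "oreml.tsv", sep="\t", index=False)
    report["oreml"] = oreml_rows

    # --- four MWAS engines on residualized probes
    engines = {}
    engines["linear"] = mw.linear_mwas(y, Wres)
    Ares = compute_orm(Wres)
    engines["linear_pc"] = mw.pc_adjusted_mwas(y, Wres, Ares, k=config.pc_k)
    engines["moa"] = mw.moa(y, Wres, orm=Ares)
    if config.run_moment:
        engines["moment"] = mw.moment(y, Wres, cfg=config.moment)
    lambdas = {}
    for name, res in engines.items():
        write_mwas(res, outdir / f"mwas_{name}.tsv")
        lambdas[name] = res.lambda_gc
    report["lambda"] = lambdas

    # --- scoring: BLUP and thresholded weights into the target cohort
    blup_w, blup_fit = sc.blup_effects(y, conf, Wstd)
    ctp_eff, _, _ = ctp_fixed_effects(y, conf, ctp_d, A, drop=drop)
    tstatus = tgt.samples["status"].to_numpy(int)
    ctp_s = sc.ctp_score(ctp_t, ctp_eff)
    auc_rows = []

    def add_auc(method, thr, m_used, scores):
        res = sc.classify(scores, tstatus)
        auc_rows.append(
            {"method": method, "p_threshold": thr, "m_used": m_used,
             "auc": res.auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
             "logit_p": res.logit_p}
        )
        return res

    blup_ps = sc.mps(tgtM, blup_w)
    add_auc("blup", None, blup_ps.n_matched, blup_ps.mps_probe)
    add_auc("ctp", None, None, ctp_s)
    # combination weights fitted on the discovery cohort's own scores
    disc_ps = sc.mps(discM, blup_w)
    disc_cs = sc.ctp_score(ctp_d, ctp_eff)
    comb = sc.combine_scores(
        [disc_ps.mps_probe, disc_cs], y, [blup_ps.mps_probe, ctp_s]
    )
    add_auc("blup_ctp", None, blup_ps.n_matched, comb)
    for name in ("linear", "moa", "moment"):
        if name not in engines:
            continue
        for wt in sc.threshold_weights(engines[name],
                                       list(config.p_thresholds)):
            if wt.m_used == 0:
                continue
            ps = sc.mps(tgtM, wt)
            add_auc(name, wt.p_threshold, ps.n_matched, ps.mps_probe)
    auc_df = pd.DataFrame(auc_rows)
    auc_df.to_csv(outdir / "auc.tsv", sep="\t", index=False)
    report["auc"] = auc_rows

    # --- cross-cohort effect correlation on the target's own scan
    if config.run_moment and tgt.methylation.n_probes:
        Wres_t = _residualize_for_mwas(tgtM, tgt.samples, ctp_t, drop)
        lin_t = mw.linear_mwas(tstatus.astype(float), Wres_t)
        lin_d = engines["linear"]
        try:
            rb_res = ev.rb_from_mwas(lin_d, lin_t)
            report["rb_linear_disc_vs_target"] = {
                "rb": rb_res.rb, "se": rb_res.se, "n": rb_res.n_probes,
            }
        except ev.UndefinedEstimateError:
            report["rb_linear_disc_vs_target"] = None

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
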