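"""Profile scores carried from discovery into the target cohort.

Builds BLUP weights and p-value-thresholded weights from the discovery
scan, scores the target cohort, adds the cell-composition score, and
writes the AUC grid to ``results/tables/auc.tsv``.
"""

import numpy as np
import pandas as pd

from mlmwas.io import read_methylation, read_mwas
from mlmwas.orm import compute_orm
from mlmwas.preprocess import design_from_covariates
from mlmwas.reml import ctp_fixed_effects
from mlmwas.scoring import (
    blup_effects,
    classify,
    combine_scores,
    ctp_score,
    mps,
    threshold_weights,
)

from common import CONFOUNDERS, DATA, MWAS_DIR, P_GRID, TABLES, std_paths


def main():
    Zd, Sd = read_methylation(*std_paths("discovery"),
                              scale_state="standardized")
    Zt, St = read_methylation(*std_paths("target"),
                              scale_state="standardized")
    y = Sd["status"].to_numpy(float)
    tstatus = St["status"].to_numpy(int)
    conf = design_from_covariates(Sd, CONFOUNDERS)[:, 1:]

    ctp_d = pd.read_csv(DATA / "discovery_ctp.tsv", sep="\t")
    ctp_t = pd.read_csv(DATA / "target_ctp.tsv", sep="\t")
    cells = [c for c in ctp_d.columns if c != "sample_id"]

    blup_w, _ = blup_effects(y, conf, Zd)
    eff, _, _ = ctp_fixed_effects(y, conf, ctp_d[cells], compute_orm(Zd))
    cs = ctp_score(ctp_t[cells], eff)

    rows = []

    def add(method, thr, m_used, scores):
        res = classify(scores, tstatus)
        rows.append({
            "method": method, "p_threshold": thr, "m_used": m_used,
            "auc": res.auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "logit_or_per_sd": res.logit_or, "logit_p": res.logit_p,
        })

    blup_ps = mps(Zt, blup_w)
    add("blup", None, blup_ps.n_matched, blup_ps.mps_probe)
    add("ctp", None, None, cs)
    # combination weights fitted on the discovery cohort's own scores
    disc_ps = mps(Zd, blup_w)
    disc_cs = ctp_score(ctp_d[cells], eff)
    comb = combine_scores([disc_ps.mps_probe, disc_cs], y.astype(int),
                          [blup_ps.mps_probe, cs])
    add("blup_ctp", None, blup_ps.n_matched, comb)

    for engine in ("linear", "moa", "moment"):
        res = read_mwas(MWAS_DIR / f"{engine}.tsv")
        for wt in threshold_weights(res, P_GRID):
            if wt.m_used == 0:
                continue
            ps = mps(Zt, wt)
            add(engine, wt.p_threshold, ps.n_matched, ps.mps_probe)

    df = pd.DataFrame(rows)
    TABLES.mkdir(parents=True, exist_ok=True)
    df.to_csv(TABLES / "auc.tsv", sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
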