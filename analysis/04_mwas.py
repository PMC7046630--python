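"""Run the four association engines on the discovery cohort.

Probes are residualized on measured confounders plus estimated cell-type
proportions before scanning.  Writes per-engine association tables under
``results/mwas/``, a lambda summary, and a top-hits table.
"""

import pandas as pd

from mlmwas.io import read_methylation, write_mwas
from mlmwas.mwas import (
    bonferroni_threshold,
    linear_mwas,
    moa,
    moment,
    pc_adjusted_mwas,
)
from mlmwas.orm import compute_orm
from mlmwas.preprocess import residualize

from common import CONFOUNDERS, DATA, MWAS_DIR, TABLES, cohort_paths, \
    std_paths


def residualized_matrix(tag: str):
    Z, S = read_methylation(*std_paths(tag), scale_state="standardized")
    ctp = pd.read_csv(DATA / f"{tag}_ctp.tsv", sep="\t")
    cells = [c for c in ctp.columns if c != "sample_id"]
    for c in cells[:-1]:  # drop one cell type compositionally
        S[f"ctp_{c}"] = ctp[c].to_numpy()
    covs = CONFOUNDERS + [f"ctp_{c}" for c in cells[:-1]]
    return residualize(Z, S, covs), S


def main():
    MWAS_DIR.mkdir(parents=True, exist_ok=True)
    TABLES.mkdir(parents=True, exist_ok=True)
    W, S = residualized_matrix("discovery")
    y = S["status"].to_numpy(float)
    A = compute_orm(W)
    engines = {
        "linear": linear_mwas(y, W),
        "linear_pc": pc_adjusted_mwas(y, W, A, k=10),
        "moa": moa(y, W, orm=A),
        "moment": moment(y, W),
    }
    thr = bonferroni_threshold(W.n_probes)
    lam_rows, top_rows = [], []
    for name, res in engines.items():
        write_mwas(res, MWAS_DIR / f"{name}.tsv")
        n_sig = int((res.table["p"] < thr).sum())
        lam_rows.append({"engine": name, "lambda": res.lambda_gc,
                         "n_bonferroni_significant": n_sig})
        top = res.table.nsmallest(10, "p").copy()
        top.insert(0, "engine", name)
        top_rows.append(top)
    lam_df = pd.DataFrame(lam_rows)
    lam_df.to_csv(TABLES / "mwas_lambda.tsv", sep="\t", index=False)
    pd.concat(top_rows).to_csv(TABLES / "mwas_top_hits.tsv", sep="\t",
                               index=False, float_format="%.6g")
    print(f"bonferroni threshold at m={W.n_probes}: {thr:.3g}")
    print(lam_df.to_string(index=False))


if __name__ == "__main__":
    main()
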