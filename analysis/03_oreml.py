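"""OREML variance-component ladder on the discovery cohort.

Fits rho^2 (proportion of phenotypic variance captured by genome-wide
methylation) under an increasing set of fixed covariates and writes
``results/tables/oreml.tsv``.
"""

import numpy as np
import pandas as pd

from mlmwas.io import read_methylation
from mlmwas.orm import compute_orm
from mlmwas.preprocess import design_from_covariates
from mlmwas.reml import reml_fit

from common import CONFOUNDERS, DATA, TABLES, std_paths


def main():
    Z, S = read_methylation(*std_paths("discovery"),
                            scale_state="standardized")
    y = S["status"].to_numpy(float)
    A = compute_orm(Z)
    ctp = pd.read_csv(DATA / "discovery_ctp.tsv", sep="\t")
    cells = [c for c in ctp.columns if c != "sample_id"]
    ctp_mat = ctp[cells[:-1]].to_numpy(float)  # drop one compositionally
    conf = design_from_covariates(S, CONFOUNDERS)[:, 1:]
    models = {
        "no_covariates": None,
        "confounders": conf,
        "ctp": ctp_mat,
        "confounders_ctp": np.column_stack([conf, ctp_mat]),
    }
    rows = []
    for label, C in models.items():
        fit = reml_fit(y, C, [A])
        rows.append({
            "model": label, "rho2": fit.rho2, "se_rho2": fit.se_rho2,
            "sigma_o2": fit.sigma_o2, "sigma_e2": fit.sigma_e2,
            "sigma_P2": fit.sigma_P2, "n_iter": fit.n_iter,
            "converged": fit.converged,
        })
    df = pd.DataFrame(rows)
    TABLES.mkdir(parents=True, exist_ok=True)
    df.to_csv(TABLES / "oreml.tsv", sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
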