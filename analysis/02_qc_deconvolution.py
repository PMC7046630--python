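"""Probe QC, standardization, cell-type deconvolution, and the stepwise
cell-composition association.

Reads the raw cohorts from ``results/data/``; writes standardized
matrices, estimated cell-type proportions, a QC count table and the
stepwise logistic table under ``results/``.
"""

import numpy as np
import pandas as pd

from mlmwas.evaluate import stepwise_ctp_logistic
from mlmwas.io import read_methylation, write_methylation
from mlmwas.preprocess import estimate_ctp, filter_probes, standardize
from mlmwas.sim import CellReference

from common import DATA, TABLES, cohort_paths, std_paths


def read_reference(path) -> CellReference:
    df = pd.read_csv(path, sep="\t")
    cell_types = [c for c in df.columns if c != "probe_id"]
    return CellReference(
        values=df[cell_types].to_numpy(float).T,
        cell_types=cell_types,
        probe_ids=df["probe_id"].tolist(),
    )


def main():
    TABLES.mkdir(parents=True, exist_ok=True)
    ref = read_reference(DATA / "cell_reference.tsv")
    qc_rows = []
    for tag in ("discovery", "target"):
        M, S = read_methylation(*cohort_paths(tag))
        Mf, rep = filter_probes(M)
        qc_rows.append({"cohort": tag, "m_input": M.n_probes,
                        "n_low_sd": rep.n_low_sd, "m_kept": rep.n_kept})
        Z = standardize(Mf)
        write_methylation(Z, S, *std_paths(tag))

        ctp = estimate_ctp(Mf, ref)
        ctp_out = ctp.copy()
        ctp_out.insert(0, "sample_id", Mf.sample_ids)
        ctp_out.to_csv(DATA / f"{tag}_ctp.tsv", sep="\t", index=False)

        truth = pd.read_csv(DATA / f"{tag}_truth_ctp.tsv", sep="\t")
        rmse = float(np.sqrt(
            ((ctp.to_numpy() - truth[ctp.columns].to_numpy()) ** 2).mean()
        ))
        print(f"{tag}: kept {rep.n_kept}/{M.n_probes} probes, "
              f"CTP RMSE vs truth {rmse:.4f}")

    pd.DataFrame(qc_rows).to_csv(TABLES / "qc_counts.tsv", sep="\t",
                                 index=False)

    ctp_d = pd.read_csv(DATA / "discovery_ctp.tsv", sep="\t")
    _, S = read_methylation(*cohort_paths("discovery"))
    cells = [c for c in ctp_d.columns if c != "sample_id"]
    stepwise = stepwise_ctp_logistic(
        ctp_d[cells] * 100.0, S["status"].to_numpy()
    )
    stepwise.to_csv(TABLES / "ctp_stepwise.tsv", sep="\t", index=False)
    print(stepwise.to_string(index=False))


if __name__ == "__main__":
    main()
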