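"""Cross-cohort agreement and replication planning.

Computes the error-corrected effect correlation (r_b) between the
discovery scan and an independent scan of the target cohort, and a table
of replication sample sizes; writes both under ``results/tables/``.
"""

import pandas as pd

from mlmwas.evaluate import UndefinedEstimateError, rb_from_mwas, \
    replication_n
from mlmwas.io import read_mwas
from mlmwas.mwas import bonferroni_threshold, linear_mwas

from common import MWAS_DIR, TABLES

import importlib

mod04 = importlib.import_module("04_mwas")


def main():
    TABLES.mkdir(parents=True, exist_ok=True)

    # independent scan of the target cohort with the naive engine
    Wt, St = mod04.residualized_matrix("target")
    tgt_scan = linear_mwas(St["status"].to_numpy(float), Wt)

    rows = []
    for engine in ("linear", "moa", "moment"):
        disc = read_mwas(MWAS_DIR / f"{engine}.tsv")
        for p_max, label in ((None, "all_shared"),
                             (1e-3, "discovery_p_below_1e-3")):
            try:
                res = rb_from_mwas(disc, tgt_scan, p_max=p_max)
                rows.append({
                    "discovery_engine": engine, "probe_set": label,
                    "rb": res.rb, "se": res.se, "n_probes": res.n_probes,
                    "clipped": res.clipped,
                })
            except (UndefinedEstimateError, ValueError) as exc:
                rows.append({
                    "discovery_engine": engine, "probe_set": label,
                    "rb": None, "se": None, "n_probes": None,
                    "clipped": None, "note": str(exc),
                })
    rb_df = pd.DataFrame(rows)
    rb_df.to_csv(TABLES / "rb.tsv", sep="\t", index=False)
    print(rb_df.to_string(index=False))

    power_rows = []
    for d in (0.14, 0.2, 0.3):
        for alpha, label in ((0.05, "nominal"),
                             (bonferroni_threshold(94), "panel_bonferroni")):
            for two_sided in (True, False):
                power_rows.append({
                    "effect_sd_units": d, "alpha": alpha,
                    "alpha_label": label,
                    "sidedness": "two" if two_sided else "one",
                    "total_n": replication_n(d, alpha, 0.8,
                                             two_sided=two_sided),
                })
    power_df = pd.DataFrame(power_rows)
    power_df.to_csv(TABLES / "replication_power.tsv", sep="\t", index=False)
    print(power_df.to_string(index=False))


if __name__ == "__main__":
    main()
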