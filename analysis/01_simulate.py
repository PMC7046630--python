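"""Simulate the discovery/target cohort pair and write all raw inputs.

Outputs under ``results/data/``: beta matrices, probe annotation, sample
tables, the cell-type reference signature, and the ground-truth tables
used only by the evaluation scripts.
"""

import pandas as pd

from mlmwas.io import write_methylation
from mlmwas.sim import simulate_cohort_pair

from common import DATA, STUDY, cohort_paths


def write_reference(ref, path):
    df = pd.DataFrame(ref.values.T, columns=ref.cell_types)
    df.insert(0, "probe_id", ref.probe_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_truth(bundle, tag):
    t = bundle.truth
    pd.DataFrame(
        {"probe_id": t.causal_probe_ids, "true_effect": t.true_effects}
    ).to_csv(DATA / f"{tag}_truth_effects.tsv", sep="\t", index=False)
    ctp = pd.DataFrame(t.true_ctp, columns=bundle.reference.cell_types)
    ctp.insert(0, "sample_id", bundle.methylation.sample_ids)
    ctp.to_csv(DATA / f"{tag}_truth_ctp.tsv", sep="\t", index=False)


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    disc, tgt = simulate_cohort_pair(STUDY)
    for tag, bundle in (("discovery", disc), ("target", tgt)):
        write_methylation(bundle.methylation, bundle.samples,
                          *cohort_paths(tag))
        write_truth(bundle, tag)
        print(f"{tag}: n={bundle.methylation.n_samples} "
              f"m={bundle.methylation.n_probes} "
              f"true_rho2={bundle.truth.true_rho2:.3f}")
    write_reference(disc.reference, DATA / "cell_reference.tsv")


if __name__ == "__main__":
    main()
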