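"""Shared paths and the study configuration for the numbered scripts.

Every script reads and writes below ``results/`` relative to the
repository root, so the sequence can be rerun end to end with
``for s in analysis/0*.py; do python "$s"; done``.
"""

from pathlib import Path

from mlmwas.sim import SimConfig

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
TABLES = ROOT / "results" / "tables"
MWAS_DIR = ROOT / "results" / "mwas"

SEED = 20_240_611

STUDY = SimConfig(
    n_cases=250,
    n_controls=250,
    m_probes=2000,
    n_causal=50,
    effect_sd=0.25,
    probe_overlap=0.9,
    seed=SEED,
)

CONFOUNDERS = ["age", "sex", "smoking_score", "batch", "chip_position"]

# p-value grid for thresholded profile scores
P_GRID = [1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0]


def cohort_paths(tag: str):
    return (
        DATA / f"{tag}_beta.tsv",
        DATA / f"{tag}_probes.opi",
        DATA / f"{tag}_samples.tsv",
    )


def std_paths(tag: str):
    return (
        DATA / f"{tag}_std.tsv",
        DATA / f"{tag}_std.opi",
        DATA / f"{tag}_std_samples.tsv",
    )
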