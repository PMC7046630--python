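import numpy as np
import pandas as pd
import pytest

from mlmwas.io import MethylationMatrix
from mlmwas.sim import SimConfig, simulate_cell_reference, simulate_cohort


def standardized_matrix(n, m, seed, n_chrom=4, spacing=30_000):
    """Random standardized matrix with probe positions for engine tests."""
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, m))
    W = (W - W.mean(axis=0)) / W.std(axis=0, ddof=0)
    chrom = [str(1 + j % n_chrom) for j in range(m)]
    bp = [1_000 + (j // n_chrom) * spacing for j in range(m)]
    annot = pd.DataFrame(
        {
            "chr": chrom,
            "probe_id": [f"p{j}" for j in range(m)],
            "bp": bp,
            "gene": "g",
            "orientation": "F",
        }
    )
    return MethylationMatrix(
        W, annot, [f"s{i}" for i in range(n)], scale_state="standardized"
    )


@pytest.fixture(scope="session")
def small_reference():
    return simulate_cell_reference(6, 500, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_reference):
    """A cohort with causal probes, CTP shift and batch structure."""
    cfg = SimConfig(
        n_cases=150, n_controls=150, m_probes=500, n_causal=25,
        effect_sd=0.3, seed=11,
    )
    M, S, T = simulate_cohort(cfg, small_reference)
    return cfg, M, S, T


@pytest.fixture(scope="session")
def null_cohort(small_reference):
    """Global null: no causal probes, no composition shift, no batch."""
    cfg = SimConfig(
        n_cases=150, n_controls=150, m_probes=500, n_causal=0,
        effect_sd=0.0, ctp_case_shift=(0.0,) * 6, batch_sd=0.0, seed=21,
    )
    M, S, T = simulate_cohort(cfg, small_reference)
    return cfg, M, S, T
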