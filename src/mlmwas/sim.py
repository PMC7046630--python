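"""Synthetic whole-blood 450K-like case-control cohort generator.

The generator emulates the confounding structure that mixed-linear-model
MWAS engines are designed to handle: probe-level beta values arise from
mixtures of cell-type-specific methylation signatures, cases and controls
differ systematically in cell composition (the classic whole-blood
confounder), slides contribute batch offsets, and a sparse set of causal
probes carries a direct case-control mean shift.  Covariates (age, sex,
smoking score) leave small footprints on subsets of probes so that
residualization has something to remove.

Values are generated on the logit scale and squashed through the inverse
logit, which keeps beta values inside [0, 1] without truncation artifacts.
Causal shifts are injected in units of the probe's own logit-scale standard
deviation, so the realized standardized case-control difference on the beta
scale tracks the configured effect size (the squashing is locally close to
linear for mid-range probes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import MethylationMatrix, PROBE_ANNOT_COLUMNS

DEFAULT_CELL_TYPES = (
    "neutrophils",
    "monocytes",
    "bcells",
    "nk",
    "cd4t",
    "cd8t",
)
# typical whole-blood composition, neutrophil dominated
DEFAULT_CTP_MEANS = (0.55, 0.09, 0.07, 0.07, 0.13, 0.09)
# case neutrophilia compensated across the other lineages (sums to zero)
DEFAULT_CTP_CASE_SHIFT = (0.03, -0.006, -0.006, -0.006, -0.006, -0.006)


class InvalidConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic case-control cohort.

    Defaults emulate a mid-size 450K whole-blood case-control study:
    balanced-ish cases/controls, sparse causal probes with standardized
    effects around 0.15 SD (the magnitude typical of the strongest hits
    in blood-based disease MWAS), a ~3 percentage-point case
    neutrophilia, slide batch effects, and ~5% near-invariant probes
    that the s.d. < 0.02 filter is meant to remove.
    """

    n_cases: int = 400
    n_controls: int = 400
    m_probes: int = 2000
    n_causal: int = 50
    effect_sd: float = 0.15
    cell_types: int = 6
    ctp_case_shift: tuple = DEFAULT_CTP_CASE_SHIFT
    batch_levels: int = 8
    batch_sd: float = 0.05
    noise_sd: float = 0.35
    frac_low_variance: float = 0.05
    probe_overlap: float = 0.9
    target_rho2: float | None = None
    ctp_concentration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "m_probes", "cell_types",
                     "batch_levels"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.n_causal < 0 or self.n_causal > self.m_probes:
            raise InvalidConfigError("need 0 <= n_causal <= m_probes")
        if not 0 <= self.probe_overlap <= 1:
            raise InvalidConfigError("probe_overlap must lie in [0, 1]")
        if not 0 <= self.frac_low_variance < 1:
            raise InvalidConfigError("frac_low_variance must lie in [0, 1)")
        shift = np.asarray(self.ctp_case_shift, dtype=float)
        if shift.shape != (self.cell_types,):
            raise InvalidConfigError(
                f"ctp_case_shift must have length {self.cell_types}"
            )
        if abs(shift.sum()) > 1e-12:
            raise InvalidConfigError(
                "ctp_case_shift must sum to 0 (proportions are a composition)"
            )
        if self.target_rho2 is not None:
            if not 0 <= self.target_rho2 < 1:
                raise InvalidConfigError("target_rho2 must lie in [0, 1)")
            if self.target_rho2 > 0 and self.n_causal == 0:
                raise InvalidConfigError(
                    "target_rho2 > 0 requires n_causal > 0"
                )


@dataclass
class CellReference:
    """Cell-type x probe matrix of mean beta values for purified cells."""

    values: np.ndarray  # K x m, entries in [0, 1]
    cell_types: list[str]
    probe_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        K, m = self.values.shape
        if len(self.cell_types) != K or len(self.probe_ids) != m:
            raise InvalidConfigError("reference labels do not match shape")
        if self.values.min() < 0 or self.values.max() > 1:
            raise InvalidConfigError("reference beta values must lie in [0, 1]")


@dataclass
class ProbeLayout:
    """Shared probe structure for cohorts drawn from the same design:
    which probes are near-invariant, which are causal (and with what
    effects), and where every probe sits on the genome."""

    lv_idx: np.ndarray
    causal_idx: np.ndarray
    effects: np.ndarray
    annot: pd.DataFrame


@dataclass
class SyntheticTruth:
    """Ground truth bundled with a simulated cohort."""

    causal_probe_ids: list[str]
    true_effects: np.ndarray  # per causal probe, standardized scale
    true_ctp: np.ndarray  # n x K proportions, rows sum to 1
    true_rho2: float
    batch_assignment: np.ndarray
    layout: ProbeLayout | None = None

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probe_id": self.causal_probe_ids, "true_effect": self.true_effects}
        )


def simulate_cell_reference(
    K: int, m: int, seed: int, cell_types: list[str] | None = None
) -> CellReference:
    """Simulate a purified-cell methylation signature matrix.

    A shared per-probe baseline (logit scale) is perturbed by cell-specific
    offsets; roughly a third of probes act as strong signature probes with
    large between-cell-type contrasts, which guarantees the signature
    submatrix has full rank K (checked).  Deterministic given ``seed``.
    """
    if K < 2:
        raise InvalidConfigError("need at least 2 cell types")
    if K > m:
        raise InvalidConfigError("need at least as many probes as cell types")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 1.2, size=m)
    offsets = rng.normal(0.0, 0.25, size=(K, m))
    n_sig = max(K, int(round(m / 3)))
    sig_idx = rng.choice(m, size=n_sig, replace=False)
    offsets[:, sig_idx] += rng.normal(0.0, 1.5, size=(K, n_sig))
    values = expit(base[None, :] + offsets)
    if np.linalg.matrix_rank(values[:, sig_idx]) < K:  # pragma: no cover
        raise InvalidConfigError("degenerate reference draw; change the seed")
    names = list(cell_types) if cell_types is not None else [
        DEFAULT_CELL_TYPES[k] if k < len(DEFAULT_CELL_TYPES) else f"cell{k}"
        for k in range(K)
    ]
    probe_ids = [f"cg{j:08d}" for j in range(m)]
    return CellReference(values=values, cell_types=names, probe_ids=probe_ids)


def _probe_positions(m: int, rng: np.random.Generator) -> pd.DataFrame:
    """Spread m probes over 22 autosomes with ~30 kb spacing plus jitter.

    1-based coordinates; consecutive probes on a chromosome sit close enough
    that a 100 kb window centred on one probe usually covers neighbours.
    """
    chroms = np.array_split(np.arange(m), 22)
    rows = []
    for c, idx in enumerate(chroms, start=1):
        pos = 1_000_000 + np.cumsum(
            rng.integers(20_000, 40_001, size=len(idx))
        )
        for k, j in enumerate(idx):
            rows.append((str(c), j, int(pos[k])))
    rows.sort(key=lambda r: r[1])
    return pd.DataFrame(rows, columns=["chr", "_j", "bp"]).drop(columns="_j")


def simulate_cohort(
    config: SimConfig,
    reference: CellReference,
    layout: ProbeLayout | None = None,
) -> tuple[MethylationMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate one case-control cohort from a cell reference.

    Returns the beta-value matrix, a sample table (status, age, sex,
    smoking_score, batch, chip_position) and the ground-truth bundle.
    Passing a ``layout`` (from another cohort's truth) reuses its probe
    roles — low-variance set, causal set, effect sizes and genomic
    annotation — so the two cohorts share the same signal; ``effect_sd``
    and ``target_rho2`` of this config are then ignored.
    """
    K = config.cell_types
    if reference.values.shape[0] != K:
        raise InvalidConfigError(
            "reference cell-type count does not match config"
        )
    m = config.m_probes
    ref = reference.values
    if ref.shape[1] < m:  # tile the reference to cover m probes
        reps = int(np.ceil(m / ref.shape[1]))
        ref = np.tile(ref, (1, reps))
    ref = ref[:, :m]

    master = np.random.SeedSequence(config.seed)
    s_ctp, s_eff, s_noise, s_batch, s_covar, s_misc = (
        np.random.default_rng(s) for s in master.spawn(6)
    )

    n = config.n_cases + config.n_controls
    status = np.zeros(n, dtype=int)
    status[: config.n_cases] = 1

    # --- cell-type proportions with case composition shift
    means = np.asarray(DEFAULT_CTP_MEANS[:K], dtype=float)
    if K != len(DEFAULT_CTP_MEANS):
        means = np.full(K, 1.0 / K)
    means = means / means.sum()
    shift = np.asarray(config.ctp_case_shift, dtype=float)
    case_means = means + shift
    if (case_means <= 0).any():
        raise InvalidConfigError("ctp_case_shift drives a mean proportion <= 0")
    conc = config.ctp_concentration
    pi = np.empty((n, K))
    pi[status == 1] = s_ctp.dirichlet(conc * case_means, size=config.n_cases)
    pi[status == 0] = s_ctp.dirichlet(conc * means, size=config.n_controls)

    # --- probe roles (draws always happen so the random streams are
    # identical with and without a shared layout)
    n_lv = int(round(config.frac_low_variance * m))
    order = s_misc.permutation(m)
    lv_idx = np.sort(order[:n_lv])
    informative = order[n_lv:]
    if config.n_causal > len(informative):
        raise InvalidConfigError("too few informative probes for n_causal")
    causal_idx = np.sort(informative[: config.n_causal])
    if layout is not None:
        if len(layout.annot) != m:
            raise InvalidConfigError("layout probe count does not match m")
        lv_idx = np.asarray(layout.lv_idx)
        causal_idx = np.asarray(layout.causal_idx)
        n_lv = len(lv_idx)

    # --- mixture signal on the logit scale
    mix = pi @ ref  # n x m, in (0, 1)
    L = logit(np.clip(mix, 1e-6, 1 - 1e-6))

    # --- covariates and their probe footprints
    age = s_covar.normal(60.0, 10.0, size=n) + 2.0 * status
    sex = (s_covar.random(n) < np.where(status == 1, 0.6, 0.5)).astype(int)
    smoking = s_covar.normal(0.0, 1.0, size=n) + 0.1 * status
    n_age = int(0.10 * m)
    n_smk = int(0.05 * m)
    n_sex = int(0.05 * m)
    age_probes = s_covar.choice(m, size=n_age, replace=False)
    smk_probes = s_covar.choice(m, size=n_smk, replace=False)
    sex_probes = s_covar.choice(m, size=n_sex, replace=False)
    L[:, age_probes] += np.outer(
        age - age.mean(), s_covar.normal(0.0, 0.01, size=n_age)
    )
    L[:, smk_probes] += np.outer(smoking, s_covar.normal(0.0, 0.1, size=n_smk))
    L[:, sex_probes] += np.outer(
        sex - sex.mean(), s_covar.normal(0.0, 0.2, size=n_sex)
    )

    # --- batch (slide) offsets: per batch x probe
    batch = s_batch.integers(config.batch_levels, size=n)
    batch_fx = s_batch.normal(0.0, config.batch_sd, size=(config.batch_levels, m))
    L += batch_fx[batch]

    # --- residual noise
    L += s_noise.normal(0.0, config.noise_sd, size=(n, m))

    # --- near-invariant probes: flat logit value plus tiny noise
    if n_lv:
        flat = s_misc.normal(0.0, 1.0, size=n_lv)
        L[:, lv_idx] = flat[None, :] + s_noise.normal(
            0.0, 0.01, size=(n, n_lv)
        )

    # --- causal case-control shifts in units of the probe's logit-scale SD
    effects = np.empty(0)
    if config.n_causal:
        signs = np.where(s_eff.random(config.n_causal) < 0.5, -1.0, 1.0)
        effects = signs * config.effect_sd
        if config.target_rho2 is not None and config.target_rho2 > 0:
            P = config.n_cases / n
            # realized variance share of the causal signal:
            #   rho2 = P(1-P) * D2 / (1 + P(1-P) * D2),  D2 = sum(effect^2)
            d2 = config.target_rho2 / ((1 - config.target_rho2) * P * (1 - P))
            effects = signs * np.sqrt(d2 / config.n_causal)
    if layout is not None:
        effects = np.asarray(layout.effects, dtype=float)
    if len(effects):
        sd_l = L[:, causal_idx].std(axis=0, ddof=0)
        L[np.ix_(status == 1, causal_idx)] += effects * sd_l

    beta = expit(L)

    annot = _probe_positions(m, s_misc)
    annot["probe_id"] = [f"cg{j:08d}" for j in range(m)]
    annot["gene"] = [f"GENE{j // 4}" for j in range(m)]
    annot["orientation"] = np.where(s_misc.random(m) < 0.5, "F", "R")
    annot = annot.loc[:, PROBE_ANNOT_COLUMNS]
    if layout is not None:
        annot = layout.annot.copy()

    sample_ids = [f"S{i:05d}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "status": status,
            "age": age,
            "sex": sex,
            "smoking_score": smoking,
            "batch": [f"slide{b}" for b in batch],
            "chip_position": [f"pos{p}" for p in s_misc.integers(12, size=n)],
        }
    )

    P = config.n_cases / n
    d2 = float(np.sum(effects**2))
    true_rho2 = P * (1 - P) * d2 / (1.0 + P * (1 - P) * d2)
    truth = SyntheticTruth(
        causal_probe_ids=[annot["probe_id"].iloc[j] for j in causal_idx],
        true_effects=effects,
        true_ctp=pi,
        true_rho2=true_rho2,
        batch_assignment=batch,
        layout=ProbeLayout(
            lv_idx=lv_idx, causal_idx=causal_idx, effects=effects,
            annot=annot,
        ),
    )
    M = MethylationMatrix(
        values=beta, probe_annot=annot, sample_ids=sample_ids,
        scale_state="beta",
    )
    return M, samples, truth


@dataclass
class CohortBundle:
    """One simulated cohort: matrix, sample table, ground truth."""

    methylation: MethylationMatrix
    samples: pd.DataFrame
    truth: SyntheticTruth
    reference: CellReference = field(repr=False, default=None)


def simulate_cohort_pair(
    config: SimConfig, target_config: SimConfig | None = None
) -> tuple[CohortBundle, CohortBundle]:
    """Simulate a discovery/target cohort pair sharing probe effects.

    Both cohorts are generated from the same cell reference and the same
    causal probes and effects (independent individuals); the target cohort
    retains a random subset of ``probe_overlap * m`` of the discovery
    probes, emulating probes lost to platform or QC differences.
    """
    ref = simulate_cell_reference(
        config.cell_types, config.m_probes, seed=config.seed + 1_000_003
    )
    disc_M, disc_S, disc_T = simulate_cohort(config, ref)
    tcfg = target_config if target_config is not None else config
    tcfg = SimConfig(
        **{
            **tcfg.__dict__,
            "seed": config.seed + 7_777_777,
            "m_probes": config.m_probes,
        }
    )
    tgt_M, tgt_S, tgt_T = simulate_cohort(tcfg, ref, layout=disc_T.layout)

    rng = np.random.default_rng(config.seed + 13)
    m = config.m_probes
    keep = np.sort(
        rng.choice(m, size=int(round(config.probe_overlap * m)), replace=False)
    )
    keep_ids = [disc_M.probe_ids[j] for j in keep]
    tgt_M = tgt_M.subset_probes(keep_ids)
    kept = set(keep_ids)
    mask = [pid in kept for pid in tgt_T.causal_probe_ids]
    tgt_T.causal_probe_ids = [
        pid for pid, k in zip(tgt_T.causal_probe_ids, mask) if k
    ]
    tgt_T.true_effects = tgt_T.true_effects[np.asarray(mask, bool)] \
        if len(mask) else tgt_T.true_effects

    return (
        CohortBundle(disc_M, disc_S, disc_T, ref),
        CohortBundle(tgt_M, tgt_S, tgt_T, ref),
    )


def simulate_oreml_phenotype(
    W: np.ndarray, rho2: float, seed: int
) -> np.ndarray:
    """Draw a phenotype from the single-component variance model.

    ``y = W u + e`` with ``u ~ N(0, rho2 / m)`` per probe and residual
    variance ``1 - rho2``, so the probe component captures a fraction
    ``rho2`` of the phenotypic variance in expectation.  ``W`` must be
    standardized (columns mean 0, variance 1).
    """
    if not 0 <= rho2 <= 1:
        raise InvalidConfigError("rho2 must lie in [0, 1]")
    n, m = W.shape
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, np.sqrt(rho2 / m), size=m)
    e = rng.normal(0.0, np.sqrt(1.0 - rho2), size=n)
    return W @ u + e
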