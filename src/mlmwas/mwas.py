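"""Per-probe association engines and the genomic-inflation diagnostic.

Four engines, in increasing order of robustness to correlated structure
(cell composition, batch) across the methylome:

``linear``
    Per-probe ordinary least squares, optionally with fixed covariates.
``linear_pc``
    OLS with the top principal components of the omics relationship
    matrix added as covariates.
``moa``
    Mixed-linear-model association: a single genome-wide random
    methylation component absorbs correlated background, and each probe is
    tested by generalized least squares against the fitted covariance
    (EMMAX-style two-step: variance components estimated once under the
    null, then reused for every probe).
``moment``
    Multi-component MLM excluding the target: probes are split into a
    most-associated group and the rest (by an initial linear scan), each
    group fitted as its own random component, and for every tested probe
    all probes within a genomic window centred on it are removed from the
    random components to avoid proximal contamination.

The genomic inflation factor lambda is the median association chi-square
over its null expectation (~0.4549 for 1 df); lambda near 1 indicates
calibrated tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io import MethylationMatrix, MwasTable, ValidationError
from .orm import ORM, compute_orm, orm_pca
from .reml import reml_fit

CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.45493642...
_P_FLOOR = 1e-300


@dataclass
class MomentConfig:
    """Settings for the multi-component window-exclusion engine.

    ``group_p_threshold`` separates the most-associated probe group from
    the rest in the initial linear scan (default 0.05).  A liberal cut is
    deliberate: the most-associated group must be large enough to absorb
    probes driven by shared confounders (cell composition, batch) into
    their own variance component, which is what keeps the engine
    calibrated when such confounding is present.
    ``window_bp`` is the total width of the exclusion region
    centred on the tested probe.  With ``refit_variance_per_probe`` off
    (the default) variance components are estimated once on the full
    groups and reused, with per-probe downdated relationship matrices
    entering the GLS solve only.
    """

    window_bp: int = 100_000
    group_p_threshold: float = 0.05
    refit_variance_per_probe: bool = False

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValidationError("window_bp must be >= 0")
        if not 0 < self.group_p_threshold < 1:
            raise ValidationError("group_p_threshold must lie in (0, 1)")


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold ``alpha / m``."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m


def genomic_lambda(p_values=None, chi2_stats=None) -> float:
    """Genomic inflation factor: median chi-square over its null median."""
    if chi2_stats is None:
        if p_values is None:
            raise ValidationError("need p-values or chi-square statistics")
        p = np.asarray(p_values, dtype=float)
        if p.size == 0:
            raise ValidationError("need at least one test")
        chi2_stats = stats.chi2.isf(np.clip(p, _P_FLOOR, 1.0), 1)
    chi2_stats = np.asarray(chi2_stats, dtype=float)
    if chi2_stats.size == 0:
        raise ValidationError("need at least one test")
    return float(np.median(chi2_stats) / CHI2_NULL_MEDIAN)


def _covariate_design(C, n: int) -> np.ndarray:
    """Intercept-plus-covariates design matrix (covariates may be None)."""
    if C is None:
        return np.ones((n, 1))
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _result_table(
    W: MethylationMatrix, b, se, p, method: str, notes=None
) -> MwasTable:
    annot = W.probe_annot
    p = np.clip(np.asarray(p, dtype=float), _P_FLOOR, 1.0)
    t = pd.DataFrame(
        {
            "Chr": annot["chr"].to_numpy(),
            "Probe": annot["probe_id"].to_numpy(),
            "bp": annot["bp"].to_numpy(),
            "Gene": annot["gene"].to_numpy(),
            "Orientation": annot["orientation"].to_numpy(),
            "b": np.asarray(b, dtype=float),
            "se": np.asarray(se, dtype=float),
            "p": p,
        }
    )
    lam = genomic_lambda(p_values=p)
    return MwasTable(table=t, method=method, lambda_gc=lam,
                     notes=list(notes or []))


def linear_mwas(y, W: MethylationMatrix, C=None) -> MwasTable:
    """Per-probe OLS scan: ``y = w_i b_i + C beta + e``.

    Slope, standard error and a two-sided t-test with ``n - p - 2``
    degrees of freedom (p covariates plus intercept plus the probe).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X0 = _covariate_design(C, n)
    p_cov = X0.shape[1] - 1
    df = n - p_cov - 2
    if df < 1:
        raise ValidationError("not enough residual degrees of freedom")
    Q, _ = np.linalg.qr(X0)
    yr = y - Q @ (Q.T @ y)
    Wr = W.values - Q @ (Q.T @ W.values)
    denom = np.einsum("ij,ij->j", Wr, Wr)
    denom0 = np.einsum("ij,ij->j", W.values, W.values)
    bad = denom <= 1e-10 * np.maximum(denom0, 1e-300)
    if bad.any():
        names = W.probe_ids[bad][:5].tolist()
        raise ValidationError(f"probes collinear with covariates: {names}")
    b = (Wr.T @ yr) / denom
    rss = float(yr @ yr) - b**2 * denom
    sigma2 = np.clip(rss, 0.0, None) / df
    se = np.sqrt(np.maximum(sigma2 / denom, 1e-300))
    tstat = b / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return _result_table(W, b, se, p, "linear")


def pc_adjusted_mwas(
    y, W: MethylationMatrix, A: ORM, k: int = 10, C=None
) -> MwasTable:
    """Linear scan with the top-k ORM principal components as covariates."""
    pcs = orm_pca(A, k)
    if C is None:
        Cfull = pcs
    else:
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Cfull = np.column_stack([C, pcs])
    out = linear_mwas(y, W, Cfull if Cfull.shape[1] else None)
    out.method = "linear_pc"
    return out


def moa(y, W: MethylationMatrix, C=None, orm: ORM | None = None) -> MwasTable:
    """Mixed-model association with a genome-wide random component.

    Two-step: (i) REML under the genome-wide model (no probe fixed effect)
    to estimate the covariance ``V = A sigma_o^2 + I sigma_e^2``; (ii) per
    probe, a GLS score-style estimate
    ``b_i = w_i' V^-1 y~ / (w_i' V^-1 w_i)`` with ``y~ = y - C beta_hat``
    and ``se_i = (w_i' V^-1 w_i)^(-1/2)``; chi-square (1 df) p-values.
    All probes are rotated into the eigenbasis of A once.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    A = orm if orm is not None else compute_orm(W)
    X0 = _covariate_design(C, n)
    fit = reml_fit(y, X0[:, 1:] if X0.shape[1] > 1 else None, [A])
    d, U = np.linalg.eigh(A.A)
    d = np.clip(d, 0.0, None)
    v = fit.sigma_o2 * d + fit.sigma_e2
    ytilde = y - X0 @ fit.beta_hat
    yt = U.T @ ytilde
    Wt = U.T @ W.values
    num = Wt.T @ (yt / v)
    den = np.einsum("ij,ij->j", Wt, Wt / v[:, None])
    b = num / den
    se = 1.0 / np.sqrt(den)
    chi2 = (b / se) ** 2
    p = stats.chi2.sf(chi2, 1)
    return _result_table(W, b, se, p, "moa")


def _window_ranges(annot: pd.DataFrame, window_bp: int) -> list[np.ndarray]:
    """Per-probe index arrays of window-excluded probes (incl. the target).

    Probes on the same chromosome within ``window_bp // 2`` (inclusive) of
    the target position.
    """
    chrom = annot["chr"].to_numpy()
    bp = annot["bp"].to_numpy(np.int64)
    half = window_bp // 2
    out: list[np.ndarray] = [None] * len(annot)  # type: ignore[list-item]
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos = bp[idx]
        order = np.argsort(pos, kind="mergesort")
        sidx, spos = idx[order], pos[order]
        lo = np.searchsorted(spos, spos - half, side="left")
        hi = np.searchsorted(spos, spos + half, side="right")
        for r, j in enumerate(sidx):
            out[j] = sidx[lo[r]:hi[r]]
    return out


def moment(
    y,
    W: MethylationMatrix,
    C=None,
    cfg: MomentConfig | None = None,
) -> MwasTable:
    """Multi-component mixed-model association excluding the target window.

    Probes are ranked by an initial linear scan and split into group 1
    (p below ``group_p_threshold``) and group 2 (the rest);
    each group forms its own random component.  For every tested probe the
    probes within the exclusion window are removed from *both* components
    (by downdating the full group relationship matrices) and the probe is
    tested as a fixed effect by GLS.  When no probe reaches the grouping
    threshold the engine falls back to a single genome-wide component
    (recorded in the table notes); a component left empty by the window
    exclusion is dropped for that probe.
    """
    cfg = cfg or MomentConfig()
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    m = W.n_probes
    thr = cfg.group_p_threshold
    lin = linear_mwas(y, W, C)
    pmap = dict(zip(lin.table["Probe"], lin.table["p"]))
    pvec = np.array([pmap[pid] for pid in W.probe_ids])
    gvec = np.where(pvec < thr, 1, 2)
    notes = []
    if not (gvec == 1).any():
        gvec = np.full(m, 2)
        notes.append("no probe passed the grouping threshold; "
                     "single-component fallback")
    labels = sorted(set(gvec.tolist()))

    X0 = _covariate_design(C, n)
    vals = W.values
    groups = {g: np.flatnonzero(gvec == g) for g in labels}
    G = {g: vals[:, idx] @ vals[:, idx].T for g, idx in groups.items()}
    m_g = {g: len(idx) for g, idx in groups.items()}
    orms_full = [
        ORM(A=G[g] / m_g[g], m=m_g[g],
            probe_ids=[W.probe_ids[j] for j in groups[g]],
            group_label=str(g))
        for g in labels
    ]
    base_fit = reml_fit(y, X0[:, 1:] if X0.shape[1] > 1 else None, orms_full)
    sig = {g: base_fit.variances[i] for i, g in enumerate(labels)}
    sig_e = base_fit.variances[-1]

    windows = _window_ranges(W.probe_annot, cfg.window_bp)
    in_group = {g: np.isin(np.arange(m), groups[g]) for g in labels}

    b = np.empty(m)
    se = np.empty(m)
    p_out = np.empty(m)
    I_n = np.eye(n)
    base_cache: dict[tuple, np.ndarray] = {}
    p0 = X0.shape[1]
    for i in range(m):
        widx = windows[i]
        drop = {g: widx[in_group[g][widx]] for g in labels}
        kcounts = tuple(len(drop[g]) for g in labels)
        active = [g for g, kk in zip(labels, kcounts)
                  if m_g[g] - kk > 0]
        if cfg.refit_variance_per_probe:
            orms_i = []
            for g in active:
                kk = len(drop[g])
                Ai = (G[g] - vals[:, drop[g]] @ vals[:, drop[g]].T) / (
                    m_g[g] - kk
                )
                orms_i.append(ORM(A=(Ai + Ai.T) / 2, m=m_g[g] - kk))
            fit_i = reml_fit(
                y, X0[:, 1:] if X0.shape[1] > 1 else None, orms_i
            )
            V = sum(
                s * o.A for s, o in zip(fit_i.variances[:-1], orms_i)
            ) + fit_i.variances[-1] * I_n
        else:
            key = tuple(
                (g, m_g[g] - len(drop[g])) for g in active
            )
            if key not in base_cache:
                Vb = sig_e * I_n.copy()
                for g, mg_new in key:
                    Vb = Vb + (sig[g] / mg_new) * G[g]
                base_cache[key] = Vb
            V = base_cache[key].copy()
            for g in active:
                kk = len(drop[g])
                if kk:
                    E = vals[:, drop[g]]
                    V -= (sig[g] / (m_g[g] - kk)) * (E @ E.T)
        w = vals[:, i]
        X = np.column_stack([X0, w])
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            V[np.diag_indices(n)] += 1e-8 * sig_e
            cf = linalg.cho_factor(V, lower=True)
        VinvX = linalg.cho_solve(cf, X)
        XtVinvX = X.T @ VinvX
        XtVinvy = VinvX.T @ y
        cov = np.linalg.inv(XtVinvX)
        beta = cov @ XtVinvy
        b[i] = beta[-1]
        se[i] = np.sqrt(cov[-1, -1])
        chi2 = (b[i] / se[i]) ** 2
        p_out[i] = stats.chi2.sf(chi2, 1)
    return _result_table(W, b, se, p_out, "moment", notes=notes)
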