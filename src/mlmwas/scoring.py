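"""BLUP probe effects, methylation profile scores, and out-of-sample
classification.

A methylation profile score (MPS) for an individual in a target cohort is
the sum of their (target-standardized) probe values weighted by per-probe
effects estimated in a discovery cohort — either BLUP joint shrinkage
estimates of all probes, or per-probe MWAS effects restricted to a p-value
threshold.  A cell-type-proportion score is the analogous weighted sum of
estimated cell proportions using fixed effects from an OREML fit.
Classification accuracy is summarized by the Mann-Whitney (midrank) AUC
with a DeLong confidence interval and a logistic-regression odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import MethylationMatrix, MwasTable, ValidationError
from .orm import compute_orm
from .reml import OremlFit, reml_fit


@dataclass
class WeightTable:
    """Per-probe scoring weights with their provenance."""

    weights: pd.Series  # index probe_id, values on the standardized scale
    source: str  # blup | moa | moment | linear | linear_pc
    p_threshold: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights.to_numpy(float)).all():
            raise ValidationError("weights must be finite")
        if self.weights.index.duplicated().any():
            raise ValidationError("duplicate probe ids in weight table")

    @property
    def m_used(self) -> int:
        return len(self.weights)


@dataclass
class ProfileScore:
    """Per-individual scores with component breakdown."""

    mps_probe: np.ndarray | None = None
    mps_ctp: np.ndarray | None = None
    probe_source: str | None = None
    n_matched: int = 0
    n_missing: int = 0

    @property
    def mps_total(self) -> np.ndarray:
        parts = [p for p in (self.mps_probe, self.mps_ctp) if p is not None]
        if not parts:
            raise ValidationError("no score components present")
        return np.sum(parts, axis=0)


def blup_effects(y, C, W: MethylationMatrix, fit: OremlFit | None = None
                 ) -> tuple[WeightTable, OremlFit]:
    """Joint shrinkage (BLUP) estimates of all probe effects.

    ``u_hat = sigma_u^2 W' V^-1 (y - C beta_hat)`` with
    ``sigma_u^2 = sigma_o^2 / m`` from the single-component REML fit; the
    computation runs in the eigenbasis of the relationship matrix.
    """
    y = np.asarray(y, dtype=float)
    A = compute_orm(W)
    if fit is None:
        fit = reml_fit(y, C, [A])
    if not fit.converged:
        raise ValidationError("REML did not converge; BLUP unavailable")
    n = y.shape[0]
    if C is None:
        X = np.ones((n, 1))
    else:
        Xc = np.asarray(C, dtype=float)
        if Xc.ndim == 1:
            Xc = Xc[:, None]
        X = np.column_stack([np.ones(n), Xc])
    ytilde = y - X @ fit.beta_hat
    d, U = np.linalg.eigh(A.A)
    d = np.clip(d, 0.0, None)
    v = fit.sigma_o2 * d + fit.sigma_e2
    sigma_u2 = fit.sigma_o2 / A.m
    u = sigma_u2 * (W.values.T @ (U @ ((U.T @ ytilde) / v)))
    weights = pd.Series(u, index=pd.Index(W.probe_ids, name="probe_id"))
    return WeightTable(weights=weights, source="blup"), fit


def threshold_weights(
    mwas: MwasTable, p_thresholds: list[float]
) -> list[WeightTable]:
    """One weight table per p-value threshold, using the MWAS effect b."""
    t = mwas.table
    out = []
    for thr in p_thresholds:
        sel = t[t["p"].to_numpy(float) < thr]
        w = pd.Series(
            sel["b"].to_numpy(float),
            index=pd.Index(sel["Probe"], name="probe_id"),
        )
        out.append(WeightTable(weights=w, source=mwas.method, p_threshold=thr))
    return out


def mps(target: MethylationMatrix, weights: WeightTable) -> ProfileScore:
    """Methylation profile scores for a target cohort.

    Target probes are standardized within the target sample; the score is
    the weighted sum over the probes shared between the weight table and
    the target matrix.  ``n_matched`` / ``n_missing`` report the overlap.
    """
    common = [p for p in weights.weights.index if p in set(target.probe_ids)]
    n_missing = weights.m_used - len(common)
    if not common:
        raise ValidationError("no weight probes present in the target cohort")
    sub = target.subset_probes(common)
    vals = sub.values
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # invariant probes contribute nothing
    Z = (vals - mu) / sd
    w = weights.weights.loc[common].to_numpy(float)
    score = Z @ w
    return ProfileScore(
        mps_probe=score,
        probe_source=weights.source,
        n_matched=len(common),
        n_missing=n_missing,
    )


def combine_scores(disc_scores, disc_status, target_scores) -> np.ndarray:
    """Discovery-fitted combination of score components.

    Regresses discovery status on the discovery-side components (each
    centered and scaled by its discovery mean/SD) by least squares --
    for a 0/1 outcome this gives the Fisher discriminant direction, and
    unlike a logistic fit it stays defined when a component separates
    the classes perfectly -- then applies the fitted coefficients to the
    target components transformed with the same discovery statistics.
    An unweighted sum of components lets a weak component dilute a
    strong one; estimating the combination weights in the discovery
    cohort keeps the weighting out-of-sample with respect to the target.
    """
    disc = [np.asarray(s, dtype=float) for s in disc_scores]
    tgt = [np.asarray(s, dtype=float) for s in target_scores]
    if len(disc) != len(tgt):
        raise ValidationError(
            "discovery and target component lists differ in length"
        )
    if len(disc) < 2:
        raise ValidationError("need at least two score components")
    status = np.asarray(disc_status, dtype=int)
    if len({len(s) for s in disc} | {len(status)}) != 1:
        raise ValidationError("discovery components must match status length")
    if status.min() == status.max():
        raise ValidationError("both classes must be present")
    cols, tcols = [], []
    for sd_, st_ in zip(disc, tgt):
        mu, sd = sd_.mean(), sd_.std(ddof=0)
        if sd == 0:
            sd = 1.0
        cols.append((sd_ - mu) / sd)
        tcols.append((st_ - mu) / sd)
    X = np.column_stack([np.ones(len(status))] + cols)
    coef, *_ = np.linalg.lstsq(X, status.astype(float), rcond=None)
    return np.column_stack(tcols) @ coef[1:]


def ctp_score(ctp: pd.DataFrame, effects: pd.Series) -> np.ndarray:
    """Weighted sum of cell-type proportions by their fixed effects."""
    missing = [c for c in effects.index if c not in ctp.columns]
    if missing:
        raise ValidationError(f"cell types not in CTP table: {missing}")
    X = ctp.loc[:, list(effects.index)].to_numpy(float)
    return X @ effects.to_numpy(float)


@dataclass
class ClassificationResult:
    """AUC with DeLong CI plus a logistic-regression summary."""

    auc: float
    ci_low: float
    ci_high: float
    auc_se: float
    logit_or: float
    logit_p: float
    n_cases: int
    n_controls: int
    covariate_adjusted: bool = False


def _auc_delong(scores: np.ndarray, status: np.ndarray):
    """Midrank AUC and its DeLong variance."""
    x = scores[status == 1]
    y = scores[status == 0]
    nx, ny = len(x), len(y)
    allv = np.concatenate([x, y])
    r = stats.rankdata(allv, method="average")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    auc = (r[:nx].sum() - nx * (nx + 1) / 2.0) / (nx * ny)
    # structural components
    v10 = (r[:nx] - rx) / ny
    v01 = 1.0 - (r[nx:] - ry) / nx
    s10 = np.var(v10, ddof=1) if nx > 1 else 0.0
    s01 = np.var(v01, ddof=1) if ny > 1 else 0.0
    var = s10 / nx + s01 / ny
    return float(auc), float(var)


def classify(scores, status, covariates=None) -> ClassificationResult:
    """Classification accuracy of a score against 0/1 status.

    AUC via the rank (Mann-Whitney) estimator with midrank ties and a
    DeLong 95% confidence interval; a logistic regression of status on the
    standardized score gives the odds ratio (per score SD) and Wald p.
    Optional covariates enter the logistic model only (the AUC stays
    unadjusted).
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    nx = int((status == 1).sum())
    ny = int((status == 0).sum())
    if nx == 0 or ny == 0:
        raise ValidationError("both classes must be present")
    auc, var = _auc_delong(scores, status)
    se = np.sqrt(max(var, 0.0))
    z = 1.959963984540054
    lo, hi = max(auc - z * se, 0.0), min(auc + z * se, 1.0)

    sd = scores.std(ddof=0)
    if sd == 0:  # constant score carries no information
        logit_or, logit_p = 1.0, 1.0
    else:
        zsc = (scores - scores.mean()) / sd
        cols = [np.ones(len(scores)), zsc]
        if covariates is not None:
            cv = np.asarray(covariates, dtype=float)
            if cv.ndim == 1:
                cv = cv[:, None]
            cols.extend(cv.T)
        X = np.column_stack(cols)
        res = sm.Logit(status, X).fit(disp=False)
        logit_or = float(np.exp(res.params[1]))
        logit_p = float(res.pvalues[1])
    return ClassificationResult(
        auc=auc, ci_low=lo, ci_high=hi, auc_se=float(se),
        logit_or=logit_or, logit_p=logit_p,
        n_cases=nx, n_controls=ny,
        covariate_adjusted=covariates is not None,
    )
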