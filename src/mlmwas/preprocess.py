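"""Probe QC, standardization, covariate residualization and cell-type
deconvolution.

The pre-analysis pipeline mirrors standard whole-blood methylation practice:
drop near-invariant probes (raw s.d. below 0.02) and probes on exclusion
lists, estimate cell-type proportions by constrained projection onto a
purified-cell reference, residualize probes on known covariates, and
standardize to per-probe mean 0 / variance 1 before any relationship-matrix
or association work.

Standardization uses the population (divisor-n) convention so that the
omics relationship matrix built from the result has mean diagonal exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .io import MethylationMatrix, ValidationError
from .sim import CellReference


class EmptyResultError(ValueError):
    """A filter removed every probe."""


class InsufficientSignatureError(ValueError):
    """Too few reference probes overlap the methylation matrix."""


@dataclass
class FilterReport:
    """Per-reason counts for a probe-filtering pass."""

    n_input: int
    n_low_sd: int
    n_excluded: int
    n_kept: int


def filter_probes(
    M: MethylationMatrix,
    sd_min: float = 0.02,
    exclude_ids: list[str] | None = None,
) -> tuple[MethylationMatrix, FilterReport]:
    """Drop probes with raw s.d. below ``sd_min`` and listed exclusions.

    Operates on beta-scale values.  The exclusion list stands in for the
    usual sex-chromosome / SNP-affected / cross-hybridizing probe lists.
    Returns the filtered matrix plus per-reason removal counts.
    """
    if M.scale_state != "beta":
        raise ValidationError("filter_probes expects beta-scale values")
    sd = M.values.std(axis=0, ddof=0)
    low = sd < sd_min
    excl = np.zeros(M.n_probes, dtype=bool)
    if exclude_ids:
        excl = np.isin(M.probe_ids, list(exclude_ids))
    keep = ~(low | excl)
    report = FilterReport(
        n_input=M.n_probes,
        n_low_sd=int(low.sum()),
        n_excluded=int((excl & ~low).sum()),
        n_kept=int(keep.sum()),
    )
    if report.n_kept == 0:
        raise EmptyResultError("all probes removed by filtering")
    out = replace(
        M,
        values=M.values[:, keep].copy(),
        probe_annot=M.probe_annot.loc[keep].reset_index(drop=True),
    )
    return out, report


def standardize(M: MethylationMatrix) -> MethylationMatrix:
    """Scale each probe to mean 0 and variance 1 (divisor n)."""
    mu = M.values.mean(axis=0)
    sd = M.values.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        bad = M.probe_ids[zero][:5].tolist()
        raise ValidationError(
            f"zero-variance probes (filter first): {bad}"
        )
    vals = (M.values - mu) / sd
    return replace(M, values=vals, scale_state="standardized")


def design_from_covariates(
    S: pd.DataFrame, covariates: list[str]
) -> np.ndarray:
    """Build an OLS design (with intercept) from sample-table columns.

    Categorical columns (object/category dtype) expand to indicator columns
    dropping the first level.
    """
    cols = [np.ones(len(S))]
    names = ["intercept"]
    for c in covariates:
        if c not in S.columns:
            raise ValidationError(f"covariate {c!r} not in sample table")
        col = S[c]
        if col.dtype == object or isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True)
            for d in dummies.columns:
                cols.append(dummies[d].to_numpy(float))
                names.append(d)
        else:
            cols.append(col.to_numpy(float))
            names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValidationError(
            f"rank-deficient covariate design; collinear columns: {bad}"
        )
    return X


def residualize(
    M: MethylationMatrix,
    S: pd.DataFrame,
    covariates: list[str],
    restandardize: bool = True,
) -> MethylationMatrix:
    """Replace each probe by its OLS residual on the covariates.

    An intercept is always included, so an empty covariate list reduces to
    mean-centering.  By default the residuals are re-standardized (per-probe
    variance 1) so downstream relationship matrices keep a unit diagonal.
    """
    X = design_from_covariates(S, covariates)
    Q, _ = np.linalg.qr(X)
    resid = M.values - Q @ (Q.T @ M.values)
    out = replace(M, values=resid, scale_state="residualized")
    if restandardize:
        sd = resid.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any():
            bad = M.probe_ids[zero][:5].tolist()
            raise ValidationError(
                f"probes fully explained by covariates: {bad}"
            )
        out = replace(out, values=resid / sd, scale_state="residualized")
    return out


def estimate_ctp(
    M: MethylationMatrix, ref: CellReference
) -> pd.DataFrame:
    """Estimate cell-type proportions by constrained projection.

    For each individual, solves ``min_pi || x - R' pi ||^2`` subject to
    ``pi >= 0`` and ``sum(pi) <= 1`` over the reference signature probes
    present in the matrix (Houseman-style reference-based deconvolution).
    Returns an individuals x cell-types DataFrame of proportions.
    """
    if M.scale_state != "beta":
        raise ValidationError("estimate_ctp expects beta-scale values")
    idx = pd.Index(M.probe_annot["probe_id"])
    locs = idx.get_indexer(ref.probe_ids)
    have = locs >= 0
    K = len(ref.cell_types)
    if have.sum() < K:
        raise InsufficientSignatureError(
            f"only {int(have.sum())} reference probes present; need >= {K}"
        )
    R = ref.values[:, have]  # K x m_common
    X = M.values[:, locs[have]]  # n x m_common
    A = R.T  # m_common x K design

    # sum(pi) <= 1 via a nonnegative slack: [A, 0] @ [pi; s] with the
    # equality sum(pi) + s = 1 enforced through SLSQP
    n = X.shape[0]
    out = np.empty((n, K))
    AtA = A.T @ A
    cons = {"type": "ineq", "fun": lambda p: 1.0 - p.sum(),
            "jac": lambda p: -np.ones(K)}
    bounds = [(0.0, 1.0)] * K
    x0_base = np.full(K, 1.0 / (K + 1))
    for i in range(n):
        Atx = A.T @ X[i]
        # warm start from the unconstrained LS solution, clipped
        try:
            ols = np.linalg.solve(AtA, Atx)
            x0 = np.clip(ols, 0.0, 1.0)
            if x0.sum() > 1:
                x0 = x0 / x0.sum()
        except np.linalg.LinAlgError:  # pragma: no cover
            x0 = x0_base

        def f(p, Atx=Atx):
            return float(p @ AtA @ p - 2.0 * p @ Atx)

        def g(p, Atx=Atx):
            return 2.0 * (AtA @ p - Atx)

        res = optimize.minimize(
            f, x0, jac=g, bounds=bounds, constraints=[cons],
            method="SLSQP", options={"maxiter": 200, "ftol": 1e-14},
        )
        out[i] = np.clip(res.x, 0.0, None)
    return pd.DataFrame(out, columns=ref.cell_types)
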