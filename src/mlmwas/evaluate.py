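"""Cross-cohort diagnostics: error-corrected effect correlation (r_b),
stepwise cell-type-proportion logistic association, and replication power.

``r_b`` estimates the correlation between two sets of probe effects while
correcting the observed variances for estimation error: the sampling noise
in each per-probe estimate inflates the naive Pearson denominator, so the
mean squared standard error is subtracted from each variance before
normalizing the covariance.  The standard error comes from a delete-one
jackknife over probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class UndefinedEstimateError(ValueError):
    """Error-corrected variance is non-positive: noise dominates signal."""


@dataclass
class RbResult:
    """Error-corrected effect-size correlation between two estimate sets."""

    rb: float
    se: float
    n_probes: int
    clipped: bool = False


def _rb_point(b1, se1, b2, se2) -> float:
    c = np.cov(b1, b2, ddof=1)[0, 1]
    v1 = np.var(b1, ddof=1) - np.mean(se1**2)
    v2 = np.var(b2, ddof=1) - np.mean(se2**2)
    if v1 <= 0 or v2 <= 0:
        raise UndefinedEstimateError(
            "error-corrected variance <= 0; effects dominated by noise"
        )
    return c / np.sqrt(v1 * v2)


def rb(b1, se1, b2, se2, overlap_correction: float = 0.0) -> RbResult:
    """Correlation of probe effects corrected for estimation error.

    ``rb = cov(b1, b2 ) / sqrt((var(b1) - mean(se1^2)) (var(b2) -
    mean(se2^2)))``; the estimate is clipped to [-1, 1] (flagged) and its
    standard error comes from a delete-one jackknife over probes.
    ``overlap_correction`` subtracts a sample-overlap covariance term from
    the numerator; it defaults to zero (independent cohorts) and exists as
    a hook only.
    """
    b1 = np.asarray(b1, float)
    b2 = np.asarray(b2, float)
    se1 = np.asarray(se1, float)
    se2 = np.asarray(se2, float)
    n = len(b1)
    if not (len(b2) == len(se1) == len(se2) == n):
        raise ValueError("effect and SE vectors must have equal length")
    if n < 10:
        raise ValueError("need at least 10 probes for an r_b estimate")
    if (se1 <= 0).any() or (se2 <= 0).any() or not (
        np.isfinite(se1).all() and np.isfinite(se2).all()
    ):
        raise ValueError("standard errors must be finite and positive")

    def point(bb1, ss1, bb2, ss2):
        r = _rb_point(bb1, ss1, bb2, ss2)
        if overlap_correction:
            v1 = np.var(bb1, ddof=1) - np.mean(ss1**2)
            v2 = np.var(bb2, ddof=1) - np.mean(ss2**2)
            r -= overlap_correction / np.sqrt(v1 * v2)
        return r

    est = point(b1, se1, b2, se2)
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            jack[i] = point(b1[mask], se1[mask], b2[mask], se2[mask])
        except UndefinedEstimateError:
            jack[i] = est
        mask[i] = True
    se = float(np.sqrt((n - 1) / n * np.sum((jack - jack.mean()) ** 2)))
    clipped = not -1.0 <= est <= 1.0
    return RbResult(
        rb=float(np.clip(est, -1.0, 1.0)), se=se, n_probes=n, clipped=clipped
    )


def rb_from_mwas(t1, t2, p_max: float | None = None,
                 select_on: int = 1) -> RbResult:
    """r_b between two MWAS tables over their shared probes.

    ``p_max`` optionally restricts to probes below that p-value in table
    ``select_on`` (1 or 2) before intersecting.
    """
    a = t1.table.set_index("Probe")
    b = t2.table.set_index("Probe")
    if p_max is not None:
        src = a if select_on == 1 else b
        keep = src.index[src["p"].to_numpy(float) < p_max]
        a = a.loc[a.index.intersection(keep)]
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    return rb(a["b"], a["se"], b["b"], b["se"])


def stepwise_ctp_logistic(
    ctp_percent: pd.DataFrame, status, alpha: float = 0.05
) -> pd.DataFrame:
    """Backward stepwise logistic regression of status on cell proportions.

    Starts from the full model (all K cell types, in percent units),
    iteratively drops the largest-p term until every remaining term has
    p < ``alpha``.  Returns one row per retained cell type with the odds
    ratio per 1-percentage-point increase, Wald 95% CI, p-value, and a
    flag for passing Bonferroni correction across the K initial tests.
    """
    status = np.asarray(status, dtype=int)
    if len(np.unique(status)) < 2:
        raise ValueError("both classes must be present")
    terms = list(ctp_percent.columns)
    K = len(terms)
    X_full = sm.add_constant(ctp_percent.to_numpy(float))
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError(
            "cell proportions are exactly compositional (collinear with "
            "the intercept); drop one cell type before the stepwise fit"
        )
    while True:
        X = sm.add_constant(ctp_percent.loc[:, terms].to_numpy(float))
        try:
            res = sm.Logit(status, X).fit(disp=False, maxiter=200)
        except Exception as exc:  # separation and friends
            raise ValueError(
                f"logistic fit failed ({exc}); consider a penalized fit"
            ) from exc
        pvals = res.pvalues[1:]
        worst = int(np.argmax(pvals))
        if pvals[worst] >= alpha and len(terms) > 1:
            terms.pop(worst)
            continue
        if pvals[worst] >= alpha:  # last remaining term not significant
            terms = []
            res = None
        break
    rows = []
    if terms and res is not None:
        z = stats.norm.ppf(0.975)
        for j, t in enumerate(terms, start=1):
            beta = res.params[j]
            se = res.bse[j]
            rows.append(
                {
                    "cell_type": t,
                    "odds_ratio": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - z * se)),
                    "ci_high": float(np.exp(beta + z * se)),
                    "p": float(res.pvalues[j]),
                    "bonferroni_significant": bool(
                        res.pvalues[j] < alpha / K
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_type", "odds_ratio", "ci_low", "ci_high", "p",
            "bonferroni_significant",
        ],
    )


def replication_n(
    effect_sd_units: float,
    alpha: float,
    power: float,
    two_sided: bool = True,
) -> int:
    """Total N of a balanced two-group design to detect a mean difference.

    Normal-approximation sample size for a standardized difference ``d``:
    per-group ``n = 2 (z_{1-alpha/2} + z_power)^2 / d^2`` (``z_{1-alpha}``
    for a one-sided test), total ``2 n`` rounded up per group.  The
    sidedness convention is explicit because reported power calculations
    rarely state it.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if effect_sd_units <= 0:
        raise ValueError("effect size must be positive")
    za = stats.norm.ppf(1 - alpha / 2) if two_sided else stats.norm.ppf(
        1 - alpha
    )
    zb = stats.norm.ppf(power)
    per_group = 2.0 * (za + zb) ** 2 / effect_sd_units**2
    return int(2 * np.ceil(per_group))
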