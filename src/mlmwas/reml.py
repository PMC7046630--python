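"""Restricted maximum likelihood for omics variance components (OREML).

Fits ``y = C beta + sum_k g_k + e`` with ``var(y) = sum_k A_k sigma_k^2 +
I sigma_e^2`` where each ``A_k`` is a relationship matrix built from
standardized methylation probes.  The headline quantity is
``rho^2 = sigma_o^2 / (sigma_o^2 + sigma_e^2)``, the proportion of
phenotypic variance captured by genome-wide methylation.  For a 0/1
case-control phenotype the estimate is reported on the observed scale
only: with methylation, associations mix causes and consequences of
disease, so no liability-scale transformation is offered.

The optimizer is average-information REML with EM fallback steps
(step-halving when an AI step would decrease the restricted likelihood)
and variance floors at ``1e-6 * var(y)``.  The single-component case is
accelerated by a one-off eigendecomposition of the relationship matrix,
which makes every iteration O(n p^2); the generic dense path handles any
number of components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .orm import ORM

_FLOOR_FACTOR = 1e-6


class RemlError(RuntimeError):
    """The REML iteration failed with unrecoverable numerical problems."""


@dataclass
class OremlFit:
    """Converged (or last-iterate) variance-component estimates.

    ``variances`` holds one entry per relationship matrix followed by the
    residual; ``sigma_o2`` is the sum of the relationship components,
    ``sigma_P2`` the sum of everything, and ``rho2 = sigma_o2 / sigma_P2``.
    ``var_cov`` is the inverse average-information matrix, used for the
    delta-method standard error of ``rho2``.
    """

    variances: np.ndarray
    sigma_o2: float
    sigma_e2: float
    rho2: float
    se_rho2: float
    beta_hat: np.ndarray
    beta_cov: np.ndarray
    loglik: float
    sigma_P2: float
    n_iter: int
    converged: bool
    var_cov: np.ndarray
    covariate_names: list[str] | None = None


class _DenseBackend:
    """Generic dense AI-REML workspace for any number of components."""

    def __init__(self, y: np.ndarray, C: np.ndarray, Ks: list[np.ndarray]):
        self.y = y
        self.C = C
        self.Ks = Ks  # includes the identity last
        self.n, self.p = C.shape

    def _common(self, theta):
        n = self.n
        V = theta[-1] * np.eye(n)
        for t, K in zip(theta[:-1], self.Ks[:-1]):
            V += t * K
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError as exc:
            raise RemlError(f"V not positive definite: {exc}") from exc
        Vinv = linalg.cho_solve(cf, np.eye(n))
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        VinvC = Vinv @ self.C
        M = self.C.T @ VinvC
        Mcf = linalg.cho_factor(M)
        logdetM = 2.0 * np.sum(np.log(np.diag(Mcf[0])))
        P = Vinv - VinvC @ linalg.cho_solve(Mcf, VinvC.T)
        Py = P @ self.y
        return P, Py, logdetV, logdetM, Mcf, VinvC

    def ll_score_ai(self, theta):
        P, Py, logdetV, logdetM, _, _ = self._common(theta)
        yPy = float(self.y @ Py)
        ll = -0.5 * (logdetV + logdetM + yPy)
        k = len(self.Ks)
        score = np.empty(k)
        KPy = []
        for i, K in enumerate(self.Ks):
            KPyi = K @ Py
            KPy.append(KPyi)
            trPK = float(np.sum(P * K))
            score[i] = -0.5 * (trPK - float(Py @ KPyi))
        AI = np.empty((k, k))
        PKPy = [P @ v for v in KPy]
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(KPy[i] @ PKPy[j])
        return ll, score, AI

    def gls(self, theta):
        _, _, _, _, Mcf, VinvC = self._common(theta)
        beta = linalg.cho_solve(Mcf, VinvC.T @ self.y)
        cov = linalg.cho_solve(Mcf, np.eye(self.p))
        return beta, cov


class _EigenBackend:
    """Single-component fast path in the eigenbasis of A.

    With ``A = U diag(d) U'`` the covariance is diagonal after rotating the
    data by ``U'``; every quantity reduces to weighted sums.
    """

    def __init__(self, y: np.ndarray, C: np.ndarray, A: np.ndarray):
        d, U = np.linalg.eigh(A)
        self.d = np.clip(d, 0.0, None)
        self.y = U.T @ y
        self.C = U.T @ C
        self.n, self.p = C.shape
        self.kvecs = [self.d, np.ones(self.n)]

    def _common(self, theta):
        v = theta[0] * self.d + theta[1]
        if (v <= 0).any():
            raise RemlError("V not positive definite in eigen path")
        B = self.C / v[:, None]
        M = self.C.T @ B
        Mcf = linalg.cho_factor(M)
        logdetV = float(np.sum(np.log(v)))
        logdetM = 2.0 * np.sum(np.log(np.diag(Mcf[0])))
        return v, B, Mcf, logdetV, logdetM

    def _apply_P(self, x, v, B, Mcf):
        return x / v - B @ linalg.cho_solve(Mcf, B.T @ x)

    def ll_score_ai(self, theta):
        v, B, Mcf, logdetV, logdetM = self._common(theta)
        Py = self._apply_P(self.y, v, B, Mcf)
        yPy = float(self.y @ Py)
        ll = -0.5 * (logdetV + logdetM + yPy)
        k = 2
        score = np.empty(k)
        KPy = []
        for i, kv in enumerate(self.kvecs):
            KPyi = kv * Py
            KPy.append(KPyi)
            # tr(P K) = sum(k/v) - tr(M^-1 B' K B)
            S = (B * kv[:, None]).T @ B
            trPK = float(np.sum(kv / v)) - float(
                np.trace(linalg.cho_solve(Mcf, S))
            )
            score[i] = -0.5 * (trPK - float(Py @ KPyi))
        AI = np.empty((k, k))
        PKPy = [self._apply_P(u, v, B, Mcf) for u in KPy]
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(KPy[i] @ PKPy[j])
        return ll, score, AI

    def gls(self, theta):
        v, B, Mcf, _, _ = self._common(theta)
        beta = linalg.cho_solve(Mcf, B.T @ self.y)
        cov = linalg.cho_solve(Mcf, np.eye(self.p))
        return beta, cov


def _profile_single(backend: _EigenBackend, floor: float) -> np.ndarray:
    """Single-component REML by profiling: for ``V = s (lambda A + I)``
    the scale ``s`` has a closed-form optimum, leaving a 1-D restricted
    likelihood in ``log lambda`` that a bounded scalar search maximizes
    reliably even when the optimum sits on the boundary."""
    from scipy import optimize

    n, p = backend.n, backend.p
    d, y, C = backend.d, backend.y, backend.C

    def neg_profile_ll(loglam: float) -> float:
        v = np.exp(loglam) * d + 1.0
        B = C / v[:, None]
        M = C.T @ B
        Mcf = linalg.cho_factor(M)
        Py = y / v - B @ linalg.cho_solve(Mcf, B.T @ y)
        yPy = float(y @ Py)
        s_hat = yPy / (n - p)
        return 0.5 * (
            (n - p) * np.log(s_hat)
            + float(np.sum(np.log(v)))
            + 2.0 * float(np.sum(np.log(np.diag(Mcf[0]))))
            + (n - p)
        )

    res = optimize.minimize_scalar(
        neg_profile_ll, bounds=(-25.0, 25.0), method="bounded",
        options={"xatol": 1e-12},
    )
    lam = float(np.exp(res.x))
    v = lam * d + 1.0
    B = C / v[:, None]
    Mcf = linalg.cho_factor(C.T @ B)
    Py = y / v - B @ linalg.cho_solve(Mcf, B.T @ y)
    s_hat = float(y @ Py) / (n - p)
    theta = np.maximum(np.array([s_hat * lam, s_hat]), floor)
    return theta, int(res.nfev)


def _prepare_design(C, n: int) -> tuple[np.ndarray, list[str]]:
    """Always-with-intercept fixed-effect design from None/array/DataFrame."""
    if C is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(C, pd.DataFrame):
        names = ["intercept"] + list(C.columns)
        X = np.column_stack([np.ones(n), C.to_numpy(float)])
        return X, names
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    # prepend an intercept unless one is already present
    has_const = any(np.ptp(C[:, j]) == 0 and C[0, j] != 0
                    for j in range(C.shape[1]))
    if has_const:
        return C, [f"c{j}" for j in range(C.shape[1])]
    X = np.column_stack([np.ones(C.shape[0]), C])
    return X, ["intercept"] + [f"c{j}" for j in range(C.shape[1])]


def reml_fit(
    y,
    C,
    orms: list[ORM],
    max_iter: int = 100,
    tol: float = 1e-8,
    method: str = "auto",
) -> OremlFit:
    """AI-REML fit of variance components for one or more ORMs.

    Parameters
    ----------
    y
        Phenotype vector (0/1 case-control or quantitative).
    C
        Fixed covariates (array or DataFrame); an intercept is added.
    orms
        Relationship matrices; an empty list fits the residual-only model.
    method
        ``"auto"`` uses the eigendecomposition fast path for a single ORM;
        ``"generic"`` forces the dense multi-component path.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    X, names = _prepare_design(C, n)
    p = X.shape[1]
    if n < p + 2:
        raise RemlError(f"n={n} too small for p={p} covariates")
    vary = float(np.var(y, ddof=0))
    if vary <= 0:
        raise RemlError("phenotype has zero variance")

    if not orms:
        Q, _ = np.linalg.qr(X)
        resid = y - Q @ (Q.T @ y)
        dof = n - p
        s2 = float(resid @ resid) / dof
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ y)
        cov = np.linalg.inv(XtX) * s2
        ll = -0.5 * (
            n * np.log(s2) + np.log(np.linalg.det(XtX / s2)) + dof
        )
        return OremlFit(
            variances=np.array([s2]), sigma_o2=0.0, sigma_e2=s2, rho2=0.0,
            se_rho2=0.0, beta_hat=beta, beta_cov=cov, loglik=ll,
            sigma_P2=s2, n_iter=0, converged=True,
            var_cov=np.array([[2.0 * s2**2 / dof]]), covariate_names=names,
        )

    k = len(orms) + 1
    floor = _FLOOR_FACTOR * vary

    if len(orms) == 1 and method == "auto":
        # profile likelihood: exact in the scale, 1-D bounded search in
        # the variance ratio — robust at the parameter boundary
        backend = _EigenBackend(y, X, orms[0].A)
        theta, n_iter = _profile_single(backend, floor)
        ll, score, AI = backend.ll_score_ai(theta)
        return _finish(backend, theta, ll, AI, n_iter, True, names, k)

    Ks = [o.A for o in orms] + [np.eye(n)]
    backend = _DenseBackend(y, X, Ks)
    theta = np.full(k, vary / k)

    ll, score, AI = backend.ll_score_ai(theta)
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        if it == 1:
            # EM first step: slow but safe far from the optimum
            proposal = np.maximum(theta + theta**2 * (2.0 * score) / n, floor)
        else:
            try:
                delta = np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                delta = theta**2 * (2.0 * score) / n
            proposal = np.maximum(theta + delta, floor)
        accepted = False
        for _ in range(12):  # step halving toward the current iterate
            try:
                ll_new, score_new, AI_new = backend.ll_score_ai(proposal)
            except RemlError:
                ll_new = -np.inf
            if ll_new >= ll - 1e-10:
                accepted = True
                break
            proposal = np.maximum(theta + 0.5 * (proposal - theta), floor)
        if not accepted:
            # damped EM never decreases the restricted likelihood
            proposal = np.maximum(theta + theta**2 * (2.0 * score) / n, floor)
            ll_new, score_new, AI_new = backend.ll_score_ai(proposal)
        if abs(ll_new - ll) < tol:
            theta, ll, score, AI = proposal, ll_new, score_new, AI_new
            converged = True
            break
        theta, ll, score, AI = proposal, ll_new, score_new, AI_new

    if converged:
        # The log-likelihood stop leaves parameter-level slack on flat
        # likelihoods; a few Newton polish steps drive the score to zero.
        scale = float(np.max(np.abs(theta)))
        for _ in range(20):
            try:
                delta = np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                break
            if np.max(np.abs(delta)) < 1e-12 * scale:
                break
            proposal = np.maximum(theta + delta, floor)
            try:
                ll_new, score_new, AI_new = backend.ll_score_ai(proposal)
            except RemlError:
                break
            if ll_new < ll - 1e-9:
                break
            theta, ll, score, AI = proposal, ll_new, score_new, AI_new

    return _finish(backend, theta, ll, AI, n_iter, converged, names, k)


def _finish(backend, theta, ll, AI, n_iter, converged, names, k) -> OremlFit:
    beta, beta_cov = backend.gls(theta)
    try:
        var_cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:  # pragma: no cover
        var_cov = np.full((k, k), np.nan)
    sigma_o2 = float(theta[:-1].sum())
    sigma_e2 = float(theta[-1])
    sigma_P2 = sigma_o2 + sigma_e2
    rho2 = sigma_o2 / sigma_P2
    grad = np.empty(k)
    grad[:-1] = sigma_e2 / sigma_P2**2
    grad[-1] = -sigma_o2 / sigma_P2**2
    se_rho2 = float(np.sqrt(max(grad @ var_cov @ grad, 0.0)))
    return OremlFit(
        variances=np.asarray(theta, dtype=float).copy(),
        sigma_o2=sigma_o2, sigma_e2=sigma_e2,
        rho2=rho2, se_rho2=se_rho2, beta_hat=beta, beta_cov=beta_cov,
        loglik=float(ll), sigma_P2=sigma_P2, n_iter=n_iter,
        converged=converged, var_cov=var_cov, covariate_names=names,
    )


def ctp_fixed_effects(
    y,
    C_base,
    ctp: pd.DataFrame,
    orm: ORM,
    drop: str | None = None,
) -> tuple[pd.Series, pd.DataFrame, OremlFit]:
    """Cell-type-proportion fixed effects from an OREML fit.

    Appends the CTP columns (dropping one compositional reference category,
    by default the last column) to the base covariates, fits the
    single-ORM variance model, and returns the CTP coefficient estimates
    with their sampling covariance plus the full fit.
    """
    cols = list(ctp.columns)
    drop = drop if drop is not None else cols[-1]
    if drop not in cols:
        raise ValueError(f"cell type {drop!r} not in CTP table")
    used = [c for c in cols if c != drop]
    ctp_used = ctp.loc[:, used]
    if C_base is None:
        C = ctp_used.copy()
    elif isinstance(C_base, pd.DataFrame):
        C = pd.concat(
            [C_base.reset_index(drop=True), ctp_used.reset_index(drop=True)],
            axis=1,
        )
    else:
        base = np.asarray(C_base, dtype=float)
        if base.ndim == 1:
            base = base[:, None]
        C = pd.DataFrame(
            np.column_stack([base, ctp_used.to_numpy(float)]),
            columns=[f"c{j}" for j in range(base.shape[1])] + used,
        )
    fit = reml_fit(y, C, [orm])
    idx = [fit.covariate_names.index(c) for c in used]
    effects = pd.Series(fit.beta_hat[idx], index=used, name="beta")
    cov = pd.DataFrame(
        fit.beta_cov[np.ix_(idx, idx)], index=used, columns=used
    )
    return effects, cov, fit
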