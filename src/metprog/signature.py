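"""Prognostic-model construction from survival-annotated expression.

Pipeline stage: univariate Cox screening of network-prioritized genes,
an L1-penalized (lasso) Cox fit with cross-validated penalty selection,
the linear risk index score = sum_g beta_g * x_g, and a median-split
stratification of the cohort into low- and high-risk groups.

The Cox partial likelihood is maximized by Newton-Raphson with Efron tie
handling; the lasso path uses the iteratively-reweighted-least-squares +
coordinate-descent scheme standard for penalized Cox models (quadratic
approximation of the Breslow partial likelihood around the current linear
predictor, then cyclic soft-thresholding on standardized covariates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFit",
    "RiskModel",
    "cox_newton",
    "univariate_cox",
    "cox_score_test",
    "screen_genes",
    "lasso_cox",
    "risk_score",
    "stratify_median",
]

_BETA_CAP = 30.0  # |beta| beyond this on the working scale flags separation


@dataclass(frozen=True)
class CoxFit:
    """Univariate Cox estimate for one gene (one row of the forest plot)."""

    gene: str
    beta: float
    hr: float
    se: float
    z: float
    p_value: float
    ci_low: float
    ci_high: float
    converged: bool = True


@dataclass(frozen=True)
class RiskModel:
    """Sparse linear risk index with its training-cohort median cut-off."""

    coefficients: dict[str, float]
    cutoff: float
    lambda_: float
    genes: tuple[str, ...]
    cv_deviance: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def active_genes(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if self.coefficients[g] != 0.0)


# ---------------------------------------------------------------------------
# Efron partial likelihood (exact Newton-Raphson fits)
# ---------------------------------------------------------------------------


def _efron_loglik(beta, X, time, event, want_derivs=True):
    """Log partial likelihood with Efron tie correction (+ grad, Hessian)."""
    eta = X @ beta
    # guard overflow on extreme working betas during step-halving
    eta = np.clip(eta, -500, 500)
    theta = np.exp(eta)
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    event_times = np.unique(time[event == 1])
    for t in event_times:
        risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        S = theta[risk].sum()
        s = theta[dead].sum()
        ll += eta[dead].sum()
        if want_derivs:
            Z = theta[risk] @ X[risk]
            z = theta[dead] @ X[dead]
            M = (theta[risk, None] * X[risk]).T @ X[risk]
            m = (theta[dead, None] * X[dead]).T @ X[dead]
            grad += X[dead].sum(axis=0)
        for ell in range(d):
            frac = ell / d
            phi = S - frac * s
            ll -= np.log(phi)
            if want_derivs:
                v = (Z - frac * z) / phi
                grad -= v
                hess += np.outer(v, v) - (M - frac * m) / phi
    return (ll, grad, hess) if want_derivs else ll


def cox_newton(
    X, time, event, *, tol: float = 1e-9, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximize the Efron partial likelihood by damped Newton-Raphson.

    Returns (beta, covariance, converged).  Monotone-likelihood separation
    (a covariate perfectly ordering the events) drives |beta| to infinity;
    it is detected by a runaway working estimate, flagged with a warning
    and the estimate capped.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate: Cox model is unidentifiable")

    sdx = X.std(axis=0)  # separation is judged on the per-SD beta scale
    beta = np.zeros(X.shape[1])
    ll, grad, hess = _efron_loglik(beta, X, time, event)
    converged = False
    for _ in range(max_iter):
        # -hess is the observed information (positive definite away from separation)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving line search
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = _efron_loglik(cand, X, time, event, want_derivs=False)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.abs(beta * sdx).max() > _BETA_CAP:
            warnings.warn(
                "monotone-likelihood separation suspected: |beta| exceeded "
                f"{_BETA_CAP} per covariate SD; estimate capped",
                RuntimeWarning,
                stacklevel=2,
            )
            beta = np.clip(beta, -_BETA_CAP / sdx, _BETA_CAP / sdx)
            ll, grad, hess = _efron_loglik(beta, X, time, event)
            break
        ll_prev = ll
        ll, grad, hess = _efron_loglik(beta, X, time, event)
        if abs(ll - ll_prev) < tol and np.abs(grad).max() < 1e-6:
            converged = True
            break
    cov = np.linalg.inv(-hess)
    return beta, cov, converged


def univariate_cox(x, time, event, gene: str = "x") -> CoxFit:
    """Single-gene Cox proportional-hazards fit with Wald inference."""
    x = np.asarray(x, dtype=float)
    beta, cov, converged = cox_newton(x, time, event)
    b = float(beta[0])
    se = float(np.sqrt(cov[0, 0]))
    z = b / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    with np.errstate(over="ignore"):  # separation-capped fits have huge se
        ci_low = float(np.exp(b - 1.959963984540054 * se))
        ci_high = float(np.exp(b + 1.959963984540054 * se))
    return CoxFit(
        gene=gene,
        beta=b,
        hr=float(np.exp(b)),
        se=se,
        z=z,
        p_value=p,
        ci_low=ci_low,
        ci_high=ci_high,
        converged=converged,
    )


def cox_score_test(x, time, event) -> float:
    """Cox score test chi-square U(0)^2 / I(0) for a single covariate.

    For a binary covariate this equals the two-group log-rank chi-square,
    a classical identity used as a cross-module consistency check.
    """
    x = np.asarray(x, dtype=float)[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _, grad, hess = _efron_loglik(np.zeros(1), x, time, event)
    return float(grad[0] ** 2 / -hess[0, 0])


def screen_genes(fits: list[CoxFit], alpha: float = 0.05) -> list[str]:
    """Genes with univariate Wald p < alpha, sorted by p ascending."""
    hits = sorted((f for f in fits if f.p_value < alpha), key=lambda f: f.p_value)
    return [f.gene for f in hits]


# ---------------------------------------------------------------------------
# Lasso-penalized Cox (IRLS + coordinate descent, Breslow ties)
# ---------------------------------------------------------------------------


def _breslow_eta_derivs(eta, time, event):
    """Breslow log partial likelihood with per-sample gradient and
    diagonal Hessian with respect to the linear predictor eta.

    Vectorized over distinct event times via sorted cumulative sums:
    the risk-set sum at t is a suffix sum of exp(eta) over time >= t,
    and the per-sample accumulators sum d_j/S_j over event times <= t_i.
    """
    eta = np.clip(eta, -500, 500)
    theta = np.exp(eta)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    prefix = np.concatenate([[0.0], np.cumsum(theta[order])])
    total = prefix[-1]

    ev_times, d = np.unique(time[event == 1], return_counts=True)
    # S_j = sum of theta over {time >= t_j}
    S = total - prefix[np.searchsorted(t_sorted, ev_times, side="left")]
    ll = float(eta[event == 1].sum() - (d * np.log(S)).sum())
    # accumulate d_j/S_j (and /S_j^2) over event times t_j <= t_i
    A = np.concatenate([[0.0], np.cumsum(d / S)])
    A2 = np.concatenate([[0.0], np.cumsum(d / S**2)])
    pos = np.searchsorted(ev_times, time, side="right")
    cum, cum2 = A[pos], A2[pos]
    grad = event - theta * cum
    wdiag = theta * cum - theta**2 * cum2
    return ll, grad, wdiag


def _cd_weighted_lasso(Xs, z, w, lam, beta, *, tol=1e-8, max_iter=1000):
    """Cyclic coordinate descent for (1/2n) sum w (z - Xs b)^2 + lam |b|_1."""
    n, p = Xs.shape
    r = z - Xs @ beta
    wx2 = (w[:, None] * Xs**2).sum(axis=0) / n
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            if wx2[j] == 0:
                continue
            bj_old = beta[j]
            rho = (w * Xs[:, j] * (r + Xs[:, j] * bj_old)).sum() / n
            bj = np.sign(rho) * max(abs(rho) - lam, 0.0) / wx2[j]
            if bj != bj_old:
                r += Xs[:, j] * (bj_old - bj)
                delta = max(delta, abs(bj - bj_old))
                beta[j] = bj
        if delta < tol:
            break
    return beta


def _lasso_path(Xs, time, event, lambdas, *, irls_iter=25, irls_tol=1e-7):
    """Warm-started lasso-Cox path on standardized covariates."""
    n, p = Xs.shape
    betas = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        for _ in range(irls_iter):
            eta = Xs @ beta
            _, grad, wdiag = _breslow_eta_derivs(eta, time, event)
            w = np.maximum(wdiag, 1e-10)
            z = eta + grad / w
            beta_old = beta.copy()
            beta = _cd_weighted_lasso(Xs, z, w, lam, beta)
            if np.abs(beta - beta_old).max() < irls_tol:
                break
        betas[i] = beta
    return betas


def _breslow_loglik(eta, time, event) -> float:
    return _breslow_eta_derivs(eta, time, event)[0]


def lasso_cox(
    X: pd.DataFrame,
    time,
    event,
    *,
    cv_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-3,
    lambda_: float | None = None,
) -> RiskModel:
    """Fit an L1-penalized Cox model and return the sparse risk index.

    Parameters
    ----------
    X
        Expression of the screened genes, genes x samples.
    time, event
        Per-sample follow-up time and 0/1 event indicator.
    cv_folds, seed
        Penalty lambda is chosen at the minimum of the cross-validated
        partial-likelihood deviance (Verweij-Van Houwelingen form),
        with event-stratified fold assignment driven by ``seed``.
    lambda_
        Fix the penalty instead of cross-validating (0 gives the
        unpenalized fit; large values give the empty model).

    Covariates are standardized internally for the coordinate descent and
    the coefficients are returned on the original expression scale.
    """
    if X.shape[0] < 2:
        raise ValueError("need at least two genes for the lasso fit")
    genes = tuple(X.index)
    Xmat = X.to_numpy(dtype=float).T  # samples x genes
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = Xmat.shape[0]
    if event.sum() < 1:
        raise ValueError("need at least one event")

    mu = Xmat.mean(axis=0)
    sd = Xmat.std(axis=0)
    if np.any(sd == 0):
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise ValueError(f"constant genes cannot enter the lasso: {bad}")
    Xs = (Xmat - mu) / sd

    _, grad0, _ = _breslow_eta_derivs(np.zeros(n), time, event)
    lam_max = np.abs(Xs.T @ grad0).max() / n
    cv_table = None
    if lambda_ is None:
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
        lambda_, cv_table = _cv_select_lambda(
            Xs, time, event, lambdas, cv_folds=cv_folds, seed=seed
        )
    lambdas_fit = np.geomspace(lam_max, max(lambda_, lam_max * 1e-6), n_lambda)
    if lambda_ <= 0:
        lambdas_fit = np.append(np.geomspace(lam_max, lam_max * 1e-4, n_lambda), 0.0)
    betas = _lasso_path(Xs, time, event, lambdas_fit)
    beta_std = betas[-1]
    beta = beta_std / sd  # original expression scale

    scores = Xmat @ beta
    cutoff = float(np.median(scores))
    return RiskModel(
        coefficients={g: float(b) for g, b in zip(genes, beta)},
        cutoff=cutoff,
        lambda_=float(lambda_),
        genes=genes,
        cv_deviance=cv_table,
    )


def _cv_select_lambda(Xs, time, event, lambdas, *, cv_folds, seed):
    """Cross-validated partial-likelihood deviance, minimised over lambda.

    Uses the Verweij-Van Houwelingen decomposition: the held-out deviance
    contribution of fold k is -2 [ ll(all; beta_-k) - ll(train_-k; beta_-k) ],
    which is well-defined even when a fold alone has too few events for a
    partial likelihood of its own.
    """
    n = Xs.shape[0]
    rng = np.random.default_rng(seed)
    # event-stratified fold assignment
    folds = np.empty(n, dtype=int)
    for status in (0, 1):
        idx = np.flatnonzero(event == status)
        perm = rng.permutation(idx)
        folds[perm] = np.arange(perm.size) % cv_folds
    dev = np.zeros((cv_folds, len(lambdas)))
    for k in range(cv_folds):
        train = folds != k
        if event[train].sum() == 0:
            raise ValueError(
                f"cross-validation fold {k}: training split has no events "
                f"(n_train={train.sum()}); reduce cv_folds"
            )
        betas = _lasso_path(Xs[train], time[train], event[train], lambdas)
        for i, b in enumerate(betas):
            ll_all = _breslow_loglik(Xs @ b, time, event)
            ll_train = _breslow_loglik(Xs[train] @ b, time[train], event[train])
            dev[k, i] = -2.0 * (ll_all - ll_train)
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    table = pd.DataFrame({"lambda": lambdas, "mean_deviance": mean_dev})
    return float(lambdas[best]), table


# ---------------------------------------------------------------------------
# Risk index and stratification
# ---------------------------------------------------------------------------


def risk_score(X: pd.DataFrame, model: RiskModel) -> pd.Series:
    """Per-sample linear risk index score_i = sum_g beta_g * x_{g,i}.

    ``X`` is genes x samples; every model gene must be present.
    """
    missing = [g for g in model.genes if g not in X.index]
    if missing:
        raise KeyError(f"model genes missing from expression matrix: {missing}")
    beta = np.array([model.coefficients[g] for g in model.genes])
    sub = X.loc[list(model.genes)].to_numpy(dtype=float)
    return pd.Series(beta @ sub, index=X.columns, name="risk_score")


def stratify_median(scores: pd.Series) -> tuple[pd.Series, float]:
    """Median-split labels: score <= median -> 'low', > median -> 'high'."""
    scores = pd.Series(scores)
    if scores.size < 2:
        raise ValueError("need at least two samples to stratify")
    cutoff = float(scores.median())
    if scores.nunique() == 1:
        raise ValueError("all risk scores identical: no median split possible")
    labels = pd.Series(
        np.where(scores > cutoff, "high", "low"), index=scores.index, name="risk_group"
    )
    return labels, cutoff
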