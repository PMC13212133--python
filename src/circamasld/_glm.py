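"""Small, fast GLM core: logistic regression by IRLS and helpers.

The mediation bootstrap refits thousands of small logistic models, so this
module keeps the per-fit overhead minimal (plain numpy, no model containers).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LogisticFit", "irls_logistic", "SeparationWarning", "CollinearityError"]


class SeparationWarning(UserWarning):
    """Raised when the likelihood appears unbounded (perfect separation)."""


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the aliased columns."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference quantities.

    Coefficients are on the log-odds scale. ``covariance`` is the inverse
    observed information at the optimum (valid when ``converged``).
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    converged: bool
    n_obs: int
    log_likelihood: float
    n_iter: int
    names: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.names.index(name)])


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # QR with column pivoting exposes which columns are aliased
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = piv[np.flatnonzero(diag <= tol)]
    if diag.size < X.shape[1]:
        bad = np.concatenate([bad, piv[diag.size:]])
    if bad.size:
        aliased = [names[j] for j in sorted(bad)]
        raise CollinearityError(f"rank-deficient design; aliased columns: {aliased}")


def irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    check_rank: bool = True,
) -> LogisticFit:
    """Fit a binomial GLM with logit link by iteratively reweighted least squares.

    Parameters
    ----------
    X
        Design matrix including the intercept column.
    y
        Binary outcome in {0, 1}.
    tol
        Convergence when the max absolute coefficient change falls below it.

    Raises
    ------
    CollinearityError
        If the design is rank deficient (aliased columns are named).

    Warns
    -----
    SeparationWarning
        When coefficients diverge or fitted probabilities collapse to 0/1;
        the fit is returned with ``converged=False``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if n <= p:
        raise ValueError("need more observations than predictors")
    if check_rank:
        _check_rank(X, list(names))

    beta = np.zeros(p)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError:
            separated = True
            break
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.max(np.abs(beta)) > 1e3:
            separated = True
            break
        if delta < tol:
            converged = True
            break
    if separated or (not converged and np.max(np.abs(beta)) > 30):
        warnings.warn(
            "possible perfect separation: coefficients diverging", SeparationWarning
        )
        converged = False

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    eps = 1e-12
    ll = float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        covariance=cov,
        converged=converged,
        n_obs=n,
        log_likelihood=ll,
        n_iter=it,
        names=list(names),
    )
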