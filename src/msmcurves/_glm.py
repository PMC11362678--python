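"""Weighted logistic regression by Newton/IRLS.

All inverse-probability and hazard models in this package are plain
maximum-likelihood logistic regressions.  The bootstrap re-fits every model
in every replicate, so the solver is written directly on numpy arrays; a
regression test checks its coefficients against statsmodels' GLM on the
same design.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

__all__ = ["ConvergenceError", "fit_logistic", "LogisticFit"]

# coefficients beyond this magnitude on a standardized-ish design indicate
# (quasi-)separation rather than a usable MLE
_SEPARATION_BOUND = 40.0


class ConvergenceError(RuntimeError):
    """Raised when a logistic model fails to reach its MLE."""


class LogisticFit:
    """Container for a fitted logistic model.

    Attributes
    ----------
    params : ndarray
        Coefficient vector, aligned with ``names``.
    names : list of str
        Term names (first is usually ``const``).
    converged : bool
    n_iter : int
    """

    def __init__(self, params, names, converged, n_iter):
        self.params = np.asarray(params, dtype=float)
        self.names = list(names)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)

    def predict(self, X):
        """Fitted event probabilities for design matrix ``X``."""
        return expit(np.asarray(X, dtype=float) @ self.params)

    def cov_sandwich(self, X, y, sample_weight=None):
        """Heteroskedasticity-robust (HC0 sandwich) covariance matrix."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        mu = self.predict(X)
        H = (X * (w * mu * (1.0 - mu))[:, None]).T @ X
        bread = np.linalg.pinv(H)
        score = X * (w * (y - mu))[:, None]
        meat = score.T @ score
        return bread @ meat @ bread

    def params_series(self):
        import pandas as pd

        return pd.Series(self.params, index=self.names)


def _neg_loglik(X, y, w, beta):
    eta = X @ beta
    # log(1 + exp(eta)) computed stably
    return -float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_logistic(X, y, sample_weight=None, *, names=None, max_iter=100,
                 tol=1e-9, start=None, name="logistic model"):
    """Fit a weighted logistic regression by Newton-Raphson with step halving.

    Parameters
    ----------
    X : (n, p) array
        Design matrix including any intercept column.
    y : (n,) array of {0, 1}
    sample_weight : (n,) array, optional
        Non-negative case weights (need not be integers).
    names : list of str, optional
        Term names; defaults to ``x0..x{p-1}``.
    name : str
        Label used in error messages.

    Returns
    -------
    LogisticFit

    Raises
    ------
    ConvergenceError
        On non-convergence or (quasi-)separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (n, p) with matching y")
    n, p = X.shape
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(p)]

    if start is not None:
        beta = np.array(start, dtype=float, copy=True)
        if beta.shape != (p,):
            raise ValueError("start vector does not match design width")
    else:
        beta = np.zeros(p)
        # warm-start the intercept at the weighted logit of the mean outcome:
        # saves several Newton steps for rare-event models
        const_col = np.flatnonzero(np.ptp(X, axis=0) == 0)
        if const_col.size and X[0, const_col[0]] != 0:
            j = const_col[0]
            ybar = float(np.clip(np.average(y, weights=w), 1e-12, 1 - 1e-12))
            beta[j] = logit(ybar) / X[0, j]

    nll = _neg_loglik(X, y, w, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        irls_w = w * mu * (1.0 - mu)
        grad = X.T @ (w * (y - mu))
        H = (X * irls_w[:, None]).T @ X
        H[np.diag_indices_from(H)] += 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"{name}: singular information matrix (collinear terms?)") from exc
        if not np.all(np.isfinite(step)):
            raise ConvergenceError(f"{name}: non-finite Newton step")
        # step halving keeps the iteration monotone in the deviance
        new_beta = beta + step
        new_nll = _neg_loglik(X, y, w, new_beta)
        halvings = 0
        while new_nll > nll + 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_nll = _neg_loglik(X, y, w, new_beta)
            halvings += 1
        improvement = nll - new_nll
        beta, nll = new_beta, new_nll
        if np.max(np.abs(step)) < tol * (1.0 + np.max(np.abs(beta))) or \
                0.0 <= improvement < 1e-10 * (abs(nll) + 0.1):
            converged = True
            break

    if not converged:
        raise ConvergenceError(f"{name}: no convergence in {max_iter} iterations")
    if np.max(np.abs(beta)) > _SEPARATION_BOUND:
        big = [names[j] for j in np.flatnonzero(np.abs(beta) > _SEPARATION_BOUND)]
        raise ConvergenceError(
            f"{name}: coefficient(s) {big} diverged — perfect or quasi-separation")
    return LogisticFit(beta, names, converged, it)
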