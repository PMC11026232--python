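"""Logistic-regression engine fitted by iteratively reweighted least squares.

Small, dependency-light Newton/IRLS maximum-likelihood fitter shared by the
association and effector-score modules.  Reports Wald standard errors from
the inverse observed information, the maximised log-likelihood (for
likelihood-ratio tests of nested models), and detects complete separation
via a diverging coefficient norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MAX_ITER = 50
LL_TOL = 1e-10
SEPARATION_NORM = 1e4


class SeparationError(RuntimeError):
    """Raised when the MLE does not exist (perfectly separated outcome)."""


class SingularDesignError(RuntimeError):
    """Raised when the design matrix is rank-deficient."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LogisticFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_iter: int

    @property
    def z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p_wald(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def ci(self, level: float = 0.95) -> np.ndarray:
        """(k, 2) array of Wald confidence limits on the log-odds scale."""
        zq = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.coef - zq * self.se, self.coef + zq * self.se])


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1+exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(X: np.ndarray, y: np.ndarray,
                 names: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit of binary ``y`` on design matrix ``X``.

    ``X`` must already include the intercept column.  Convergence is declared
    when the log-likelihood improves by less than 1e-10; separation is flagged
    when the coefficient norm diverges.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    n, k = X.shape
    if y.min() == y.max():
        raise SeparationError("outcome is constant")
    if n < k:
        raise SingularDesignError(f"n={n} rows for {k} parameters")
    if np.linalg.matrix_rank(X) < k:
        raise SingularDesignError("design matrix is rank deficient")

    beta = np.zeros(k)
    ll_old = _loglik(y, X @ beta)
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtWX = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("information matrix singular "
                                  "(separated or degenerate data)") from exc
        beta_new = beta + step
        ll_new = _loglik(y, X @ beta_new)
        # step-halving guards the occasional overshoot on near-separated data
        halvings = 0
        while ll_new < ll_old - 1e-12 and halvings < 30:
            step *= 0.5
            beta_new = beta + step
            ll_new = _loglik(y, X @ beta_new)
            halvings += 1
        beta = beta_new
        if np.linalg.norm(beta) > SEPARATION_NORM:
            raise SeparationError("coefficient norm diverged: "
                                  "complete or quasi-complete separation")
        if abs(ll_new - ll_old) < LL_TOL:
            ll_old = ll_new
            break
        ll_old = ll_new
    else:
        raise ConvergenceError(f"IRLS did not converge in {MAX_ITER} iterations")

    if ll_old > -1e-8 * n:
        # a perfectly predicted sample: the MLE lies at infinity
        raise SeparationError("log-likelihood at zero: complete separation")

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return LogisticFit(names=names or [f"x{i}" for i in range(k)],
                       coef=beta, se=se, cov=cov, loglik=ll_old, n=n, n_iter=it)


def likelihood_ratio_test(full: LogisticFit, reduced: LogisticFit) -> tuple[float, int, float]:
    """LR statistic, df and p comparing nested fits (full ⊃ reduced)."""
    df = len(full.coef) - len(reduced.coef)
    if df <= 0:
        raise ValueError("full model must have more parameters than reduced")
    lr = 2.0 * (full.loglik - reduced.loglik)
    lr = max(lr, 0.0)
    return lr, df, float(stats.chi2.sf(lr, df))
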