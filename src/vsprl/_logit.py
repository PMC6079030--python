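"""Small, fast binomial-logit maximum likelihood core.

Newton-Raphson on the (concave) log-likelihood, with an optional Jeffreys
(Firth) penalty used as the fallback under quasi-complete separation.  The
grid-profile estimation of the learning rate refits this model hundreds to
thousands of times per participant, so the implementation is deliberately
minimal: dense numpy, no per-call object construction.

Cross-checked in the test suite against statsmodels' Logit and against
brute-force likelihood-grid maximization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOG_EPS = 1e-300


def log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Bernoulli log-likelihood of a logit model at ``beta``."""
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.sum(np.logaddexp(0.0, eta)))


@dataclass
class LogitFit:
    params: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    separated: bool
    penalized: bool
    rank_deficient: bool
    bse: np.ndarray | None = None


def _newton(
    X: np.ndarray,
    y: np.ndarray,
    penalized: bool,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, bool, int, float]:
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    it = 0
    ridge = 1e-10
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        H = XtW @ X
        score = X.T @ (y - p)
        if penalized:
            # Firth adjustment: score += 0.5 * diag-hat correction
            try:
                Hinv = np.linalg.inv(H + ridge * np.eye(k))
            except np.linalg.LinAlgError:
                Hinv = np.linalg.pinv(H)
            h = np.einsum("ij,jk,ik->i", X, Hinv, XtW.T)
            score = X.T @ (y - p + h * (0.5 - p))
        try:
            step = np.linalg.solve(H + ridge * np.eye(k), score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # dampen exploding steps (separation)
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        ll = log_likelihood(X, y, beta)
        if penalized:
            sign, logdet = np.linalg.slogdet(H + ridge * np.eye(k))
            ll = ll + 0.5 * logdet
        if abs(ll - ll_old) < tol and np.max(np.abs(step)) < 1e-6:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return beta, converged, it, ll_old


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    firth_fallback: bool = True,
    compute_bse: bool = False,
) -> LogitFit:
    """Fit a binomial logit by Newton-Raphson.

    Detects quasi-complete separation (divergent coefficients) and, when
    ``firth_fallback`` is set, refits with the Jeffreys-penalized likelihood
    instead of returning divergent estimates.  Rank deficiency of the design
    is flagged; affected coefficients come from the pseudoinverse path.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    rank_deficient = np.linalg.matrix_rank(X) < k

    beta, converged, it, _ = _newton(X, y, penalized=False, tol=tol, max_iter=max_iter)
    separated = bool(np.max(np.abs(beta)) > 25.0) or not converged
    penalized = False
    if separated and firth_fallback:
        beta, converged, it, _ = _newton(
            X, y, penalized=True, tol=tol, max_iter=max_iter
        )
        penalized = True
    llf = log_likelihood(X, y, beta)

    bse = None
    if compute_bse:
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        H = (X.T * (p * (1 - p))) @ X
        try:
            bse = np.sqrt(np.diag(np.linalg.inv(H)))
        except np.linalg.LinAlgError:
            bse = np.sqrt(np.diag(np.linalg.pinv(H)))

    return LogitFit(
        params=beta,
        llf=llf,
        converged=converged,
        n_iter=it,
        separated=separated,
        penalized=penalized,
        rank_deficient=rank_deficient,
        bse=bse,
    )
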