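"""Little's test of missing completely at random (MCAR).

Rows of a numeric table are grouped by their missingness pattern.  Under
multivariate normality, the grand mean vector and covariance matrix are
estimated by expectation-maximization (EM) over the incomplete data, and
the statistic

    d2 = sum_j n_j (ybar_obs,j - mu_obs,j)' Sigma_obs,j^{-1} (ybar_obs,j - mu_obs,j)

compares each pattern's observed-variable means with the EM grand means.
Under MCAR, d2 is asymptotically chi-square with df = sum_j k_j - k,
where k_j counts the observed variables in pattern j and k the total
number of variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["McarResult", "em_mvn", "little_mcar_test"]


@dataclass(frozen=True)
class McarResult:
    chi2: float
    df: int
    P: float
    n_patterns: int
    n_used: int
    mean: np.ndarray
    cov: np.ndarray


def _patterns(mask: np.ndarray) -> dict[tuple, np.ndarray]:
    """Row indices grouped by observed-variable pattern (True = observed)."""
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(mask):
        groups.setdefault(tuple(row), []).append(i)
    return {k: np.array(v) for k, v in groups.items()}


def em_mvn(
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """ML mean and covariance of a multivariate normal with missing values.

    Plain EM: the E-step fills each row's missing block with its
    conditional expectation given the observed block and accumulates the
    conditional covariance; the M-step re-estimates mu and Sigma (ML,
    divisor n).  Convergence is declared when the observed-data
    log-likelihood improves by less than ``tol``.

    Returns (mu, Sigma, observed-data loglik, n_iterations).
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    obs = ~np.isnan(X)
    if not obs.any(axis=0).all():
        raise ValueError("every variable must be observed at least once")
    mu = np.nanmean(X, axis=0)
    diffs = np.where(obs, X - mu, 0.0)
    sigma = (diffs.T @ diffs) / n
    sigma[np.diag_indices_from(sigma)] += 1e-6 * np.trace(sigma) / k + 1e-12

    groups = _patterns(obs)
    prev_ll = -np.inf
    ll = -np.inf
    for it in range(1, max_iter + 1):
        filled = np.where(obs, X, 0.0)
        cc = np.zeros((k, k))
        ll = 0.0
        for pattern, idx in groups.items():
            o = np.array(pattern)
            m = ~o
            rows = X[np.ix_(idx, o)]
            s_oo = sigma[np.ix_(o, o)]
            chol = np.linalg.cholesky(s_oo)
            dev = rows - mu[o]
            half = np.linalg.solve(chol, dev.T)
            ll += (
                -0.5 * len(idx) * (o.sum() * np.log(2 * np.pi)
                                   + 2 * np.log(np.diag(chol)).sum())
                - 0.5 * float((half**2).sum())
            )
            if m.any():
                s_mo = sigma[np.ix_(m, o)]
                coef = np.linalg.solve(s_oo, s_mo.T).T        # S_mo S_oo^-1
                cond_mean = mu[m] + dev @ coef.T
                filled[np.ix_(idx, m)] = cond_mean
                cond_cov = sigma[np.ix_(m, m)] - coef @ s_mo.T
                cc[np.ix_(m, m)] += len(idx) * cond_cov
        mu = filled.mean(axis=0)
        centered = filled - mu
        sigma = (centered.T @ centered + cc) / n
        if ll - prev_ll < tol and it > 1:
            break
        prev_ll = ll
    return mu, sigma, float(ll), it


def little_mcar_test(
    table: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> McarResult:
    """Little's chi-square MCAR test on a numeric table with missing cells.

    Rows with all values missing are dropped.  Complete data (a single
    pattern) yields chi2 = 0, df = 0, P = 1 — there is no evidence to
    assess, not a rejection.
    """
    X = table.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    keep = ~np.isnan(X).all(axis=1)
    X = X[keep]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 usable rows")
    k = X.shape[1]
    mu, sigma, _, _ = em_mvn(X, tol=tol, max_iter=max_iter)
    groups = _patterns(~np.isnan(X))
    if len(groups) == 1:
        return McarResult(chi2=0.0, df=0, P=1.0, n_patterns=1,
                          n_used=X.shape[0], mean=mu, cov=sigma)
    d2 = 0.0
    df = 0
    for pattern, idx in groups.items():
        o = np.array(pattern)
        ybar = X[np.ix_(idx, o)].mean(axis=0)
        dev = ybar - mu[o]
        s_oo = sigma[np.ix_(o, o)]
        try:
            sol = np.linalg.solve(s_oo, dev)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular pattern covariance") from exc
        d2 += len(idx) * float(dev @ sol)
        df += int(o.sum())
    df -= k
    return McarResult(chi2=float(d2), df=df, P=float(stats.chi2.sf(d2, df)),
                      n_patterns=len(groups), n_used=X.shape[0],
                      mean=mu, cov=sigma)
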