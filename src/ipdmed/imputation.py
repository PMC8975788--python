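"""Multivariate-normal multiple imputation via EM with bootstrapped parameter draws.

The engine mirrors the EMB (expectation-maximization with bootstrapping) workflow:
maximum-likelihood mean/covariance of an incomplete data matrix are found by EM under a
missing-at-random assumption; parameter uncertainty for multiple imputation comes from
re-running EM on nonparametric bootstrap resamples of the rows; each incomplete row of
the *original* matrix is then completed with a draw from the conditional normal of its
missing block given its observed block. Binary columns are imputed on the continuous
scale and rounded to the nearer of {0, 1}.

Observed cells are never altered: the m completed matrices agree exactly on every
originally observed entry. Inference downstream is by bootstrap, so pooling across
imputations only needs the arithmetic mean of the point estimates (Rubin's rule for
point estimates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["MvnParams", "ImputationSet", "em_mvn", "draw_imputations", "pool_point_estimates"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MvnParams:
    """EM estimate of a multivariate-normal mean and covariance."""

    mu: np.ndarray
    sigma: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    loglik_trace: np.ndarray | None = None


@dataclass
class ImputationSet:
    """m completed copies of one incomplete data matrix.

    Observed cells are identical across copies and equal to the source; only
    originally missing cells differ between copies.
    """

    m: int
    completed: list[np.ndarray]
    source_params: list[MvnParams]


def _patterns(mask: np.ndarray):
    """Group row indices by missingness pattern (mask True = missing)."""
    if mask.shape[0] == 0:
        return []
    _, inverse = np.unique(mask, axis=0, return_inverse=True)
    out = []
    for g in np.unique(inverse):
        rows = np.nonzero(inverse == g)[0]
        out.append((rows, mask[rows[0]]))
    return out


def em_mvn(
    data: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 1e-6,
    keep_trace: bool = False,
) -> MvnParams:
    """EM maximum-likelihood mean/covariance of an incomplete data matrix.

    Missing cells are NaN. Convergence is declared when the maximum absolute
    change across all mean and covariance entries falls below ``tol``; if
    ``max_iter`` is reached first, the last iterate is returned with
    ``converged=False`` and a warning. ``ridge`` is added to the diagonal of the
    observed-block covariance before factorization (numerical guard on small or
    nearly collinear blocks); the reported ``sigma`` itself is the unridged
    M-step estimate, so on complete data the result equals the sample moments
    (divisor n) exactly.

    Rows with no observed cell are dropped with a warning; a fully missing
    column is an error.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D matrix")
    mask = np.isnan(X)
    if mask.all(axis=0).any():
        bad = np.nonzero(mask.all(axis=0))[0].tolist()
        raise ValueError(f"column(s) {bad} are fully missing")
    empty_rows = mask.all(axis=1)
    if empty_rows.any():
        warnings.warn(f"dropping {int(empty_rows.sum())} fully missing row(s)", stacklevel=2)
        X, mask = X[~empty_rows], mask[~empty_rows]
    obs_per_var = (~mask).sum(axis=0)
    if (obs_per_var < 2).any():
        bad = np.nonzero(obs_per_var < 2)[0].tolist()
        raise ValueError(f"column(s) {bad} observed for fewer than 2 rows")

    n, p = X.shape
    mu = np.nanmean(X, axis=0)
    var0 = np.nanvar(X, axis=0)
    var0 = np.where(var0 > 0, var0, 1.0)
    sigma = np.diag(var0)

    groups = _patterns(mask)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: expected sufficient statistics, accumulated per missingness pattern
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        loglik = 0.0
        for rows, miss in groups:
            Xg = X[rows]
            o = ~miss
            if not miss.any():
                s1 += Xg.sum(axis=0)
                s2 += Xg.T @ Xg
                # observed-data loglik for complete rows
                c, low = cho_factor(sigma + ridge * np.eye(p), lower=True)
                dev = Xg - mu
                z = cho_solve((c, low), dev.T)
                logdet = 2.0 * np.log(np.diag(c)).sum()
                loglik += -0.5 * (len(rows) * (p * _LOG2PI + logdet) + np.einsum("ij,ji->", dev, z))
                continue
            oi = np.nonzero(o)[0]
            mi = np.nonzero(miss)[0]
            Soo = sigma[np.ix_(oi, oi)] + ridge * np.eye(len(oi))
            Som = sigma[np.ix_(oi, mi)]
            Smm = sigma[np.ix_(mi, mi)]
            c, low = cho_factor(Soo, lower=True)
            dev = Xg[:, oi] - mu[oi]
            # conditional mean of missing block given observed block
            B = cho_solve((c, low), Som)  # (|o| x |m|)
            cond_mean = mu[mi] + dev @ B
            cond_cov = Smm - Som.T @ B
            full = Xg.copy()
            full[:, mi] = cond_mean
            s1 += full.sum(axis=0)
            s2 += full.T @ full
            s2[np.ix_(mi, mi)] += len(rows) * cond_cov
            z = cho_solve((c, low), dev.T)
            logdet = 2.0 * np.log(np.diag(c)).sum()
            loglik += -0.5 * (
                len(rows) * (len(oi) * _LOG2PI + logdet) + np.einsum("ij,ji->", dev, z)
            )
        mu_new = s1 / n
        sigma_new = s2 / n - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        trace.append(loglik)
        delta = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", stacklevel=2)
    return MvnParams(
        mu=mu,
        sigma=sigma,
        loglik=float(trace[-1]),
        iterations=it,
        converged=converged,
        loglik_trace=np.asarray(trace) if keep_trace else None,
    )


def _conditional_impute(
    X: np.ndarray,
    mask: np.ndarray,
    params: MvnParams,
    rng: np.random.Generator,
    binary_cols: tuple[int, ...],
    ridge: float,
) -> np.ndarray:
    """Complete X by drawing missing blocks from their conditional normals."""
    out = X.copy()
    mu, sigma = params.mu, params.sigma
    for rows, miss in _patterns(mask):
        if not miss.any():
            continue
        oi = np.nonzero(~miss)[0]
        mi = np.nonzero(miss)[0]
        Soo = sigma[np.ix_(oi, oi)] + ridge * np.eye(len(oi))
        Som = sigma[np.ix_(oi, mi)]
        Smm = sigma[np.ix_(mi, mi)]
        c, low = cho_factor(Soo, lower=True)
        B = cho_solve((c, low), Som)
        cond_mean = mu[mi] + (X[np.ix_(rows, oi)] - mu[oi]) @ B
        cond_cov = Smm - Som.T @ B
        cond_cov = 0.5 * (cond_cov + cond_cov.T)
        # guard tiny negative eigenvalues from finite-precision Schur complements
        evals, evecs = np.linalg.eigh(cond_cov)
        L = evecs * np.sqrt(np.clip(evals, 0.0, None))
        z = rng.standard_normal((len(rows), len(mi)))
        out[np.ix_(rows, mi)] = cond_mean + z @ L.T
    for j in binary_cols:
        col_missing = mask[:, j]
        if col_missing.any():
            out[col_missing, j] = (out[col_missing, j] >= 0.5).astype(float)
    return out


def draw_imputations(
    data: np.ndarray,
    m: int = 10,
    rng: np.random.Generator | int | None = None,
    binary_cols: tuple[int, ...] = (),
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 1e-6,
) -> ImputationSet:
    """Generate m completed copies of an incomplete matrix (EMB algorithm).

    For each copy: bootstrap the rows, run :func:`em_mvn` on the resample to get
    a parameter draw, then impute every incomplete row of the *original* matrix
    from the conditional normal of its missing block given its observed block
    under those parameters. Columns listed in ``binary_cols`` are rounded to the
    nearer of {0, 1} after imputation.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.asarray(data, dtype=float)
    mask = np.isnan(X)
    completed: list[np.ndarray] = []
    params_list: list[MvnParams] = []
    if not mask.any():
        return ImputationSet(m=m, completed=[X.copy() for _ in range(m)], source_params=[])
    n = X.shape[0]
    for _ in range(m):
        boot = rng.integers(0, n, size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-convergence inside a draw is tolerated
            params = em_mvn(X[boot], tol=tol, max_iter=max_iter, ridge=ridge)
        completed.append(_conditional_impute(X, mask, params, rng, binary_cols, ridge))
        params_list.append(params)
    return ImputationSet(m=m, completed=completed, source_params=params_list)


def pool_point_estimates(estimates) -> np.ndarray:
    """Combine per-imputation parameter vectors by their arithmetic mean.

    Rubin's rule for point estimates; within/between variances are not needed
    because interval estimation is by bootstrap.
    """
    arrs = [np.asarray(e, dtype=float) for e in estimates]
    if not arrs:
        raise ValueError("no estimates to pool")
    length = arrs[0].shape
    if any(a.shape != length for a in arrs):
        raise ValueError("estimate vectors have mismatched lengths")
    return np.mean(arrs, axis=0)
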