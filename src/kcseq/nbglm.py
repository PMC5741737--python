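"""Batched negative-binomial log-linear model fitting.

All fits share one design matrix across genes, so the iteratively
reweighted least squares updates are vectorised over genes: each iteration
solves a stack of small (p x p) systems. The NB variance is mu + phi*mu^2
with a per-gene dispersion phi; phi -> 0 recovers the Poisson model.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import qr
from scipy.special import gammaln

_MIN_MU = 1e-8
_POISSON_PHI = 1e-8


def drop_aliased_columns(X: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Return X restricted to a maximal linearly independent column subset.

    Column order is preserved; uses pivoted QR rank detection.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        return X
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * max(diag[0], 1.0)).sum())
    keep = np.sort(piv[:rank])
    return X[:, keep]


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Log-likelihood per gene; y, mu are (G, S), phi is (G,) or scalar."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, _MIN_MU)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))
    out = np.empty(y.shape[0])
    pois = phi < _POISSON_PHI
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = (yp * np.log(mp) - mp - gammaln(yp + 1.0)).sum(axis=1)
    nb = ~pois
    if nb.any():
        yn, mn = y[nb], mu[nb]
        r = 1.0 / phi[nb][:, None]  # size parameter
        out[nb] = (
            gammaln(yn + r) - gammaln(r) - gammaln(yn + 1.0)
            + yn * np.log(mn / (mn + r)) + r * np.log(r / (mn + r))
        ).sum(axis=1)
    return out


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray | float,
    max_iter: int = 60,
    tol: float = 1e-8,
):
    """Fit log-link NB GLMs for all genes at once.

    Parameters
    ----------
    y : (G, S) counts
    X : (S, p) design, assumed full column rank
    offset : (S,) or (G, S) log effective library sizes
    phi : per-gene dispersion, (G,) or scalar

    Returns
    -------
    beta : (G, p), mu : (G, S), loglik : (G,), converged : (G,) bool
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    G, S = y.shape
    p = X.shape[1]
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (G, S))
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,))

    # start from a regularised log-linear least squares fit
    z0 = np.log((y + 0.5) / np.exp(offset))
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, p)

    eye = np.eye(p) * 1e-10
    ll_old = np.full(G, -np.inf)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    mu = np.maximum(np.exp(beta @ X.T + offset), _MIN_MU)

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        eta = beta[idx] @ X.T + offset[idx]
        eta = np.clip(eta, -60.0, 60.0)
        mu_a = np.maximum(np.exp(eta), _MIN_MU)
        w = mu_a / (1.0 + phi[idx, None] * mu_a)  # Fisher working weights
        z = (eta - offset[idx]) + (y[idx] - mu_a) / mu_a
        XtWX = np.einsum("si,gs,sj->gij", X, w, X) + eye
        XtWz = np.einsum("si,gs,gs->gi", X, w, z)
        beta_new = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        step = beta_new - beta[idx]
        # halve steps that worsen the likelihood (rare, safeguards big counts)
        ll_new = nb_loglik(y[idx], np.exp(np.clip(beta_new @ X.T + offset[idx], -60, 60)), phi[idx])
        worse = ll_new < ll_old[idx] - 1e-10
        for _half in range(8):
            if not worse.any():
                break
            step[worse] *= 0.5
            cand = beta[idx] + step
            ll_new = np.where(
                worse,
                nb_loglik(y[idx], np.exp(np.clip(cand @ X.T + offset[idx], -60, 60)), phi[idx]),
                ll_new,
            )
            beta_new = np.where(worse[:, None], cand, beta_new)
            worse = ll_new < ll_old[idx] - 1e-10
        beta[idx] = beta_new
        done = np.abs(ll_new - ll_old[idx]) < tol * (np.abs(ll_new) + 1.0)
        ll_old[idx] = ll_new
        converged[idx[done]] = True
        active[idx[done]] = False

    mu = np.maximum(np.exp(np.clip(beta @ X.T + offset, -60, 60)), _MIN_MU)
    loglik = nb_loglik(y, mu, phi)
    return beta, mu, loglik, converged


def cox_reid_apl(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray | float,
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood of phi, per gene.

    The adjustment subtracts half the log-determinant of the Fisher
    information of the mean parameters at the fitted values, profiling
    them out so the dispersion estimate is not biased by their count.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    G = y.shape[0]
    phi_b = np.broadcast_to(np.asarray(phi, dtype=float), (G,))
    _, mu, ll, _ = fit_nb_glm(y, X, offset, phi_b)
    w = mu / (1.0 + phi_b[:, None] * mu)
    XtWX = np.einsum("si,gs,sj->gij", X, w, X) + np.eye(X.shape[1]) * 1e-10
    sign, logdet = np.linalg.slogdet(XtWX)
    return ll - 0.5 * logdet
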