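"""Batched negative-binomial GLM fitting (log link) via IRLS.

All genes share one design matrix; coefficients are fitted gene-wise with
iteratively reweighted least squares, max 50 iterations, deviance tolerance
1e-8.  Variance function is mu + alpha * mu^2 with a fixed per-gene alpha
(alpha <= ALPHA_POISSON is treated as Poisson).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

MAX_ITER = 50
DEV_TOL = 1e-8
ETA_CLIP = 30.0
ALPHA_POISSON = 1e-8


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; Poisson limit for tiny alpha.

    y, mu: (G, n); alpha: (G,).  Returns (G,).
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-300)
    alpha = np.asarray(alpha, dtype=float)
    out = np.empty(y.shape[0])
    pois = alpha <= ALPHA_POISSON
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = np.sum(yp * np.log(mp) - mp - gammaln(yp + 1), axis=1)
    nb = ~pois
    if nb.any():
        yn, mn = y[nb], mu[nb]
        r = (1.0 / alpha[nb])[:, None]
        out[nb] = np.sum(
            gammaln(yn + r)
            - gammaln(r)
            - gammaln(yn + 1)
            + r * np.log(r / (r + mn))
            + yn * np.log(mn / (r + mn)),
            axis=1,
        )
    return out


def nb_deviance_residuals(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Signed square-root deviance contributions, shape (G, n)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-300)
    alpha = np.asarray(alpha, dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
        nb_term = np.where(
            alpha > ALPHA_POISSON,
            (y + 1.0 / np.maximum(alpha, ALPHA_POISSON))
            * np.log((mu + 1.0 / np.maximum(alpha, ALPHA_POISSON)) / (y + 1.0 / np.maximum(alpha, ALPHA_POISSON))),
            mu - y,  # Poisson limit
        )
    dev = 2.0 * (ylogy + nb_term)
    dev = np.maximum(dev, 0.0)
    return np.sign(y - mu) * np.sqrt(dev)


def fit_nb_glm(
    y: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
) -> dict:
    """Fit log-link NB GLMs for all genes at once.

    Parameters
    ----------
    y : (G, n) nonnegative counts
    design : (n, p) design matrix (must include intercept if wanted)
    offset : (n,) log-scale offset (log size factors)
    alpha : (G,) fixed NB dispersions

    Returns
    -------
    dict with keys ``beta`` (G, p), ``se`` (G, p), ``loglik`` (G,),
    ``mu`` (G, n), ``converged`` (G,) bool, ``ok`` (G,) bool (fit usable).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (y.shape[1],))
    alpha = np.asarray(alpha, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    if n != X.shape[0]:
        raise ValueError("design rows must equal number of samples")

    ok = y.sum(axis=1) > 0
    beta = np.zeros((G, p))
    se = np.full((G, p), np.nan)
    converged = np.zeros(G, dtype=bool)
    mu = np.full((G, n), np.nan)
    loglik = np.full(G, np.nan)
    if not ok.any():
        return dict(beta=beta, se=se, loglik=loglik, mu=mu, converged=converged, ok=ok)

    idx = np.where(ok)[0]
    yk = y[idx]
    ak = alpha[idx]
    # init from log counts
    z0 = np.log(yk + 0.5) - offset[None, :]
    pinv = np.linalg.pinv(X)
    bk = z0 @ pinv.T

    dev_old = np.full(idx.size, np.inf)
    active = np.ones(idx.size, dtype=bool)
    sing = np.zeros(idx.size, dtype=bool)
    for _ in range(MAX_ITER):
        if not active.any():
            break
        eta = np.clip(bk @ X.T + offset[None, :], -ETA_CLIP, ETA_CLIP)
        muk = np.exp(eta)
        w = muk / (1.0 + ak[:, None] * muk)
        z = (eta - offset[None, :]) + (yk - muk) / muk
        a_idx = np.where(active)[0]
        wa = w[a_idx]
        xtwx = np.einsum("gn,np,nq->gpq", wa, X, X)
        xtwz = np.einsum("gn,np,gn->gp", wa, X, z[a_idx])
        xtwx += 1e-10 * np.eye(p)[None, :, :]
        try:
            bnew = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            bnew = np.stack(
                [np.linalg.lstsq(m, v, rcond=None)[0] for m, v in zip(xtwx, xtwz)]
            )
        bad = ~np.all(np.isfinite(bnew), axis=1)
        if bad.any():
            sing[a_idx[bad]] = True
            bnew[bad] = bk[a_idx[bad]]
        bk[a_idx] = bnew
        eta = np.clip(bk @ X.T + offset[None, :], -ETA_CLIP, ETA_CLIP)
        muk = np.exp(eta)
        dev = -2.0 * nb_loglik(yk, muk, ak)
        delta = np.abs(dev - dev_old)
        tol = DEV_TOL * (np.abs(dev) + 0.1)
        active = active & ~(delta < tol)
        dev_old = dev

    eta = np.clip(bk @ X.T + offset[None, :], -ETA_CLIP, ETA_CLIP)
    muk = np.exp(eta)
    w = muk / (1.0 + ak[:, None] * muk)
    xtwx = np.einsum("gn,np,nq->gpq", w, X, X) + 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(xtwx)
    sek = np.sqrt(np.maximum(np.einsum("gpp->gp", cov), 0.0))

    beta[idx] = bk
    se[idx] = sek
    mu[idx] = muk
    loglik[idx] = nb_loglik(yk, muk, ak)
    converged[idx] = ~active & ~sing
    ok[idx[sing]] = False
    return dict(beta=beta, se=se, loglik=loglik, mu=mu, converged=converged, ok=ok)
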