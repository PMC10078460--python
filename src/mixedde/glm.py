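"""Negative-binomial GLM (NB2, log link) fitted by IRLS with ML size
parameter.

This is the fixed-effects-only counterpart of the mixed model in
:mod:`mixedde.glmm`: intercept + two-level condition, optional per-sample
log offset, variance ``mu + mu^2 / theta``. Coefficients are obtained by
alternating iteratively reweighted least squares for ``beta`` with Newton
updates of ``log theta``; it is implemented independently of the Laplace
machinery so the two can be cross-checked against each other.

`fit_nb_glm_many` vectorizes the same algorithm across all genes of a
matrix, exploiting that every gene shares the one design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, polygamma

_ETA_CLIP = 30.0


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta) -> np.ndarray:
    """Elementwise NB2 log-likelihood."""
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(np.maximum(mu, 1e-300) / (theta + mu))
    )


@dataclass
class NBGLMResults:
    """Fitted NB GLM for one gene."""

    params: np.ndarray  # (intercept, condition) on the natural-log scale
    bse: np.ndarray
    theta: float
    llf: float
    converged: bool
    n_iter: int

    @property
    def log2fc(self) -> float:
        return float(self.params[1] / np.log(2.0))


class NBGLM:
    """Per-gene negative-binomial GLM: ``log mu = b0 + b1*cond + offset``.

    Parameters
    ----------
    y : array of counts for one gene.
    cond : 0/1 condition indicator per sample.
    offset : per-sample log offset (default zero).
    """

    def __init__(self, y, cond, offset=None):
        self.y = np.asarray(y, dtype=float)
        self.cond = np.asarray(cond, dtype=float)
        n = self.y.size
        self.offset = np.zeros(n) if offset is None else np.asarray(offset, float)
        if self.y.size != self.cond.size or self.y.size != self.offset.size:
            raise ValueError("y, cond and offset must have equal length")

    def fit(
        self,
        max_iter: int = 100,
        tol: float = 1e-10,
        theta_fixed: float | None = None,
    ) -> NBGLMResults:
        out = fit_nb_glm_many(
            self.y[None, :], self.cond, self.offset,
            max_iter=max_iter, tol=tol, theta_fixed=theta_fixed,
        )
        return NBGLMResults(
            params=out["beta"][0],
            bse=out["bse"][0],
            theta=float(out["theta"][0]),
            llf=float(out["llf"][0]),
            converged=bool(out["converged"][0]),
            n_iter=int(out["n_iter"][0]),
        )


def _poisson_init(Y: np.ndarray, cond: np.ndarray, offset: np.ndarray):
    """Closed-form Poisson GLM start: per-group count/exposure ratios."""
    e = np.exp(offset)
    s0 = np.maximum(Y[:, cond == 0].sum(axis=1), 0.25)
    s1 = np.maximum(Y[:, cond == 1].sum(axis=1), 0.25)
    e0 = e[cond == 0].sum()
    e1 = e[cond == 1].sum()
    b0 = np.clip(np.log(s0 / e0), -_ETA_CLIP, _ETA_CLIP)
    b1 = np.clip(np.log(s1 / e1) - b0, -_ETA_CLIP, _ETA_CLIP)
    return b0, b1


def _theta_moments(Y, mu):
    """Method-of-moments NB size parameter per gene."""
    phi = ((Y - mu) ** 2 - mu).sum(axis=1) / np.maximum((mu**2).sum(axis=1), 1e-12)
    return 1.0 / np.clip(phi, 1e-4, 1e4)


def fit_nb_glm_many(
    Y: np.ndarray,
    cond: np.ndarray,
    offset: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    theta_fixed: float | None = None,
) -> dict:
    """Fit the NB GLM to every row of ``Y`` (genes x samples) at once.

    Returns arrays ``beta`` (m x 2), ``bse`` (m x 2, expected-information
    standard errors), ``theta``, ``llf``, ``converged``, ``n_iter``.
    With ``theta_fixed`` the size parameter is held constant and only the
    coefficients are estimated.
    """
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    cond = np.asarray(cond, dtype=float)
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    b0, b1 = _poisson_init(Y, cond, offset)
    eta = b0[:, None] + b1[:, None] * cond + offset
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    if theta_fixed is None:
        theta = _theta_moments(Y, mu)
    else:
        theta = np.full(m, float(theta_fixed))

    ll_old = nb_loglik(Y, mu, theta[:, None]).sum(axis=1)
    converged = np.zeros(m, dtype=bool)
    n_iter = np.zeros(m, dtype=np.int64)

    for it in range(max_iter):
        # IRLS step for beta (2x2 normal equations, closed form)
        w = mu * theta[:, None] / (mu + theta[:, None])
        z = (eta - offset) + (Y - mu) / np.maximum(mu, 1e-300)
        sw = w.sum(axis=1)
        swd = (w * cond).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swdz = (w * cond * z).sum(axis=1)
        det = np.maximum(sw * swd - swd**2, 1e-300)
        nb0 = (swd * swz - swd * swdz) / det
        nb1 = (sw * swdz - swd * swz) / det
        nb0 = np.clip(nb0, -_ETA_CLIP, _ETA_CLIP)
        nb1 = np.clip(nb1, -_ETA_CLIP, _ETA_CLIP)

        eta = nb0[:, None] + nb1[:, None] * cond + offset
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))

        # two damped Newton steps on log theta
        for _ in range(2 if theta_fixed is None else 0):
            th = theta[:, None]
            dldt = (
                digamma(Y + th) - digamma(th)
                + np.log(th / (th + mu))
                + (mu - Y) / (mu + th)
            ).sum(axis=1)
            d2ldt2 = (
                polygamma(1, Y + th) - polygamma(1, th)
                + 1.0 / th - 2.0 / (th + mu)
                + (Y + th) / (th + mu) ** 2
            ).sum(axis=1)
            # chain rule to log theta
            g = theta * dldt
            h = theta**2 * d2ldt2 + g
            step = np.where(h < 0, -g / h, np.sign(g) * 0.5)
            step = np.clip(step, -1.5, 1.5)
            theta = np.clip(theta * np.exp(step), 1e-4, 1e6)

        ll = nb_loglik(Y, mu, theta[:, None]).sum(axis=1)
        active = ~converged
        still = np.abs(ll - ll_old) <= tol * (np.abs(ll_old) + 1.0)
        close = (np.abs(nb0 - b0) < 1e-8) & (np.abs(nb1 - b1) < 1e-8)
        converged |= active & still & close
        n_iter[active] = it + 1
        b0, b1, ll_old = nb0, nb1, ll
        if converged.all():
            break

    # expected-information covariance at the optimum
    w = mu * theta[:, None] / (mu + theta[:, None])
    sw = w.sum(axis=1)
    swd = (w * cond).sum(axis=1)
    det = np.maximum(sw * swd - swd**2, 1e-300)
    var0 = swd / det
    var1 = sw / det
    bse = np.sqrt(np.column_stack([var0, var1]))

    return {
        "beta": np.column_stack([b0, b1]),
        "bse": bse,
        "theta": theta,
        "llf": ll_old,
        "converged": converged,
        "n_iter": n_iter,
    }
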