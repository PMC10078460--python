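"""Per-gene negative-binomial generalized linear mixed model.

The model for one gene's counts across samples is

    y_j | b ~ NB2(mu_j, theta),   log mu_j = beta0 + beta1 * cond_j
                                             + offset_j + b_{g(j)}

with a random intercept ``b_g ~ N(0, sigma2)`` over the levels of a
grouping factor (individual, gender, or one level per sample for
observation-level extra variation). ``beta1`` is the condition contrast
(second level minus reference) on the natural-log scale. Fitting
maximizes the Laplace-approximate marginal likelihood (kernels in
:mod:`mixedde._laplace`); with no grouping factor the model reduces to an
NB GLM fitted through the same machinery with ``b = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from ._laplace import _fit_gene, fit_genes_batch
from .data import MixedDEError

_FIELDS = (
    "beta0", "beta1", "se0", "se1", "theta", "sigma2",
    "loglik", "converged", "boundary", "n_fev",
)


def _encode_groups(groups, n: int):
    """Integer group codes plus CSR membership arrays for the kernels."""
    if groups is None:
        gidx = np.zeros(n, dtype=np.int64)
        q = 1
    else:
        vals = list(groups)
        if len(vals) != n:
            raise MixedDEError("grouping vector length mismatch")
        levels = list(dict.fromkeys(vals))
        pos = {v: i for i, v in enumerate(levels)}
        gidx = np.array([pos[v] for v in vals], dtype=np.int64)
        q = len(levels)
    order = np.argsort(gidx, kind="stable").astype(np.int64)
    starts = np.zeros(q + 1, dtype=np.int64)
    np.add.at(starts, gidx + 1, 1)
    starts = np.cumsum(starts).astype(np.int64)
    return gidx, order, starts, q


@dataclass
class NBGLMMResults:
    """Laplace-fit results for one gene.

    ``params`` holds (intercept, condition) on the natural-log scale;
    ``bse`` their standard errors from the observed-information matrix of
    the marginal likelihood.
    """

    params: np.ndarray
    bse: np.ndarray
    theta: float
    sigma2: float
    llf: float
    converged: bool
    boundary: bool
    n_iter: int
    df_resid: float = np.inf

    def wald_test(self, coef: int = 1) -> tuple[float, float]:
        return wald_test(self, coef)

    @property
    def log2fc(self) -> float:
        return float(self.params[1] / np.log(2.0))

    def summary(self) -> str:
        stat, p = self.wald_test()
        lines = [
            "NB GLMM (Laplace) fit",
            f"  intercept  {self.params[0]: .4f}  (se {self.bse[0]:.4f})",
            f"  condition  {self.params[1]: .4f}  (se {self.bse[1]:.4f})",
            f"  theta      {self.theta: .4f}",
            f"  sigma2     {self.sigma2: .4f}",
            f"  loglik     {self.llf: .4f}",
            f"  Wald z = {stat:.4f}, p = {p:.4g}",
            f"  converged={self.converged} boundary={self.boundary}",
        ]
        return "\n".join(lines)


class NBGLMM:
    """Negative-binomial mixed model for a single gene.

    Parameters
    ----------
    y : counts for one gene, one per sample.
    cond : 0/1 condition indicator (or an (n, 2) design whose second
        column is the indicator).
    groups : per-sample labels of the random grouping factor, or None for
        a fixed-effects-only NB GLM.
    offset : per-sample log offset, typically log(size factor x library).
    """

    def __init__(self, y, cond, groups=None, offset=None):
        self.y = np.ascontiguousarray(y, dtype=np.float64)
        cond = np.asarray(cond, dtype=np.float64)
        if cond.ndim == 2:
            if cond.shape[1] != 2 or not np.allclose(cond[:, 0], 1.0):
                raise MixedDEError(
                    "fixed design must be intercept + condition indicator"
                )
            cond = cond[:, 1]
        self.cond = np.ascontiguousarray(cond)
        n = self.y.size
        if np.any(self.y < 0):
            raise MixedDEError("negative counts")
        if set(np.unique(self.cond)) - {0.0, 1.0}:
            raise MixedDEError("condition indicator must be 0/1")
        self.offset = (
            np.zeros(n) if offset is None
            else np.ascontiguousarray(offset, dtype=np.float64)
        )
        self.has_re = groups is not None
        self.gidx, self.order, self.starts, self.q = _encode_groups(groups, n)

    def fit(self) -> NBGLMMResults:
        out = np.empty(10)
        _fit_gene(
            self.y, self.cond, self.offset, self.gidx, self.order,
            self.starts, self.q, self.has_re, out,
        )
        return NBGLMMResults(
            params=out[0:2].copy(),
            bse=out[2:4].copy(),
            theta=float(out[4]),
            sigma2=float(out[5]),
            llf=float(out[6]),
            converged=bool(out[7]),
            boundary=bool(out[8]),
            n_iter=int(out[9]),
            df_resid=float(max(self.y.size - 2, 1)),
        )


def fit_nb_glmm(y, cond, groups=None, offset=None) -> NBGLMMResults:
    """Convenience wrapper: build an :class:`NBGLMM` and fit it."""
    return NBGLMM(y, cond, groups=groups, offset=offset).fit()


def fit_matrix(Y, cond, groups=None, offset=None) -> np.ndarray:
    """Fit the per-gene model to every row of ``Y``.

    Returns an (m, 10) array with columns beta0, beta1, se0, se1, theta,
    sigma2, loglik, converged, boundary, n_fev.
    """
    Y = np.ascontiguousarray(Y, dtype=np.float64)
    n = Y.shape[1]
    cond = np.ascontiguousarray(cond, dtype=np.float64)
    offset = (
        np.zeros(n) if offset is None
        else np.ascontiguousarray(offset, dtype=np.float64)
    )
    has_re = groups is not None
    gidx, order, starts, q = _encode_groups(groups, n)
    return fit_genes_batch(Y, cond, offset, gidx, order, starts, q, has_re)


def wald_test(fit, coef: int = 1, df: float | None = None) -> tuple[float, float]:
    """Wald statistic and two-sided p-value for one coefficient.

    The statistic is beta/SE; its reference distribution is Student t
    with the fit's residual degrees of freedom (n - 2), the small-sample
    calibration that keeps the test near its nominal level when the NB
    size parameter is itself estimated from few replicates. ``df=inf``
    gives the asymptotic normal reference.
    """
    if not getattr(fit, "converged", True):
        return (np.nan, np.nan)
    beta = fit.params[coef]
    se = fit.bse[coef]
    if not np.isfinite(se) or se <= 0:
        return (np.nan, np.nan)
    stat = beta / se
    if df is None:
        df = getattr(fit, "df_resid", np.inf)
    if np.isinf(df):
        p = 2.0 * scipy.stats.norm.sf(abs(stat))
    else:
        p = 2.0 * scipy.stats.t.sf(abs(stat), df=df)
    return (float(stat), float(p))
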