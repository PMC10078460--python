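"""Overdispersion diagnostics and the biological coefficient of variation.

Two dataset-level diagnostics:

* per-gene equi/overdispersion labels from the Pearson chi-square ratio of
  a Poisson log-linear fit (intercept + condition): ratio <= 1 means the
  gene is consistent with Poisson (equidispersed), ratio > 1 overdispersed;
* a single common negative-binomial dispersion ``phi`` for the whole
  matrix, whose square root is the biological coefficient of variation
  (BCV) — the between-replicate coefficient of variation of underlying
  expression.

The common dispersion maximizes the summed NB2 log-likelihood over all
genes with gene-and-condition-specific means fixed at group averages of
library-size-equalized counts; this is a plug-in-profile analogue of
conditional maximum likelihood and agrees with it at the first decimal
place, which is the precision BCVs are usually reported at.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
from scipy.special import gammaln

from .data import CountMatrix, DesignTable, MixedDEError

PHI_LOG_BOUNDS = (np.log(1e-6), np.log(10.0))


@dataclass
class DispersionSummary:
    gene_ids: list[str]
    pearson_ratio: np.ndarray
    labels: np.ndarray  # "equidispersed" | "overdispersed"
    n_equidispersed: int
    n_overdispersed: int


@dataclass
class BCVEstimate:
    common_dispersion: float

    @property
    def bcv(self) -> float:
        return float(np.sqrt(self.common_dispersion))


def _group_means(values: np.ndarray, cond: np.ndarray) -> np.ndarray:
    """Per-gene fitted means from a saturated-in-condition Poisson fit.

    For a log-linear model with intercept + condition the MLE fitted value
    in each cell is its condition-group average.
    """
    mu = np.empty_like(values, dtype=float)
    for g in (0, 1):
        cols = cond == g
        mu[:, cols] = values[:, cols].mean(axis=1, keepdims=True)
    return mu


def pearson_ratio(
    y: np.ndarray, cond: np.ndarray, intercept_only: bool = False
) -> float:
    """Pearson chi-square ratio of a Poisson GLM fit to one gene.

    ratio = sum((y - mu)^2 / mu) / (n - p) with p = 2 for the
    intercept + condition model (1 if ``intercept_only``). Cells with a
    fitted mean of zero are skipped and the degrees of freedom reduced;
    an undefined ratio (df <= 0) degenerates to 0 (equidispersed).
    """
    y = np.asarray(y, dtype=float)
    cond = np.asarray(cond)
    n = y.size
    if n < 3:
        raise MixedDEError("insufficient replicates for dispersion ratio")
    if intercept_only:
        mu = np.full(n, y.mean())
    else:
        mu = np.empty(n)
        for g in (0, 1):
            sel = cond == g
            if sel.any():
                mu[sel] = y[sel].mean()
    ok = mu > 0
    n_params = 1 if intercept_only else len({int(c) for c in cond[ok]})
    df = int(ok.sum()) - n_params
    if df <= 0:
        return 0.0
    chi2 = float(((y[ok] - mu[ok]) ** 2 / mu[ok]).sum())
    return chi2 / df


def classify_matrix(
    matrix: CountMatrix, design: DesignTable, intercept_only: bool = False
) -> DispersionSummary:
    """Label every gene equi- or overdispersed from its Pearson ratio."""
    vals = matrix.values
    cond = design.condition_indicator
    n = vals.shape[1]
    if intercept_only:
        mu = np.repeat(vals.mean(axis=1, keepdims=True), n, axis=1)
    else:
        mu = _group_means(vals, cond)
    ok = mu > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(ok, (vals - mu) ** 2 / np.where(ok, mu, 1.0), 0.0)
    chi2 = cells.sum(axis=1)
    if intercept_only:
        n_params = np.ones(vals.shape[0])
    else:
        n_params = sum(
            (mu[:, cond == g][:, :1] > 0).ravel().astype(int) for g in (0, 1)
        )
    df = ok.sum(axis=1) - n_params
    ratio = np.where(df > 0, chi2 / np.maximum(df, 1), 0.0)
    labels = np.where(ratio <= 1.0, "equidispersed", "overdispersed")
    return DispersionSummary(
        gene_ids=list(matrix.genes),
        pearson_ratio=ratio,
        labels=labels,
        n_equidispersed=int((labels == "equidispersed").sum()),
        n_overdispersed=int((labels == "overdispersed").sum()),
    )


def _nb_loglik_total(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Summed NB2 log-likelihood over cells with positive mean.

    Accepts real-valued (library-equalized) counts through the gamma
    continuous extension of the NB pmf.
    """
    ok = mu > 0
    y, mu = y[ok], mu[ok]
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1.0)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def estimate_bcv(matrix: CountMatrix, design: DesignTable) -> BCVEstimate:
    """Common NB dispersion and BCV for a count matrix.

    Counts are first equalized to the geometric-mean library size, group
    means are fixed at condition averages, and ``phi`` maximizes the summed
    NB log-likelihood by Brent search on log phi. A Cox-Reid adjustment
    (half the summed log information of the fitted means) removes the
    (r-1)/r downward bias the plug-in means would otherwise cause at
    small replicate counts.
    """
    vals = matrix.values
    if vals.sum() == 0:
        raise MixedDEError("cannot estimate dispersion of an all-zero matrix")
    cond = design.condition_indicator
    for g in (0, 1):
        if (cond == g).sum() < 2:
            raise MixedDEError("need >= 2 samples per condition for BCV")
    libs = vals.sum(axis=0)
    if (libs == 0).any():
        raise MixedDEError("zero-total library")
    gm = np.exp(np.log(libs).mean())
    eq = vals * (gm / libs)
    mu = _group_means(eq, cond)
    reps = np.array([(cond == 0).sum(), (cond == 1).sum()], dtype=float)

    # group means with positive fitted value, and their replicate counts,
    # for the Cox-Reid correction that removes the plug-in-mean bias
    mu_groups = np.column_stack(
        [eq[:, cond == g].mean(axis=1) for g in (0, 1)]
    )
    pos = mu_groups > 0

    def neg_ll(logphi: float) -> float:
        theta = 1.0 / np.exp(logphi)
        ll = _nb_loglik_total(eq, mu, theta)
        # CR term: -0.5 * sum log Fisher information of each fitted mean
        w = mu_groups * theta / (mu_groups + theta)
        ll -= 0.5 * np.log(reps * np.where(pos, w, 1.0))[pos].sum()
        return -ll

    res = scipy.optimize.minimize_scalar(
        neg_ll, bounds=PHI_LOG_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    return BCVEstimate(common_dispersion=float(np.exp(res.x)))
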