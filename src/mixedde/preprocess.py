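"""Count-matrix preprocessing: scale correction, RLE normalization, and
expression filters.

The pipeline runs, in order:

1. **Scale correction** — every library (column) is rescaled so its total
   equals the smallest library total: ``a*_ij = (lambda / nu_j) * a_ij``
   with ``nu_j`` the column sums and ``lambda = min_j nu_j``.
2. **RLE normalization** — median-of-ratios size factors computed against
   per-gene geometric means over genes expressed in every sample.
3. **Filters** on the raw counts of each gene, attributed to the first
   stage that removes it:
   all-zero genes; partially expressed genes whose counts are not
   significantly different from an all-zero vector (two-sided rank-sum
   test); genes with identical counts in every sample; genes whose mean
   counts-per-million is at or below a threshold.

Filtering never alters retained values; the stage tallies partition the
input gene set exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb

import numpy as np
import scipy.stats

from .data import CountMatrix, DesignTable, MixedDEError

#: pooled sample count at or below which the rank-sum null is enumerated
#: exactly instead of using the tie-corrected normal approximation
EXACT_RANKSUM_MAX_N = 8


@dataclass
class PreprocessConfig:
    wilcoxon_alpha: float = 0.05
    cpm_threshold: float = 1.0
    run_scale_correction: bool = True
    run_rle: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.wilcoxon_alpha < 1:
            raise MixedDEError("wilcoxon_alpha must be in (0, 1)")
        if self.cpm_threshold < 0:
            raise MixedDEError("cpm_threshold must be >= 0")


@dataclass
class PreprocessReport:
    """Per-stage gene tallies and bookkeeping from a preprocessing run."""

    n_input_genes: int = 0
    n_expressed_all_replicates: int = 0
    n_unexpressed: int = 0
    n_partial_removed: int = 0
    n_partial_kept: int = 0
    n_constant_removed: int = 0
    n_lowcpm_removed: int = 0
    n_retained: int = 0
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    retained_ids: list[str] = field(default_factory=list)
    deg_loss_percent: float | None = None
    size_factors: dict[str, float] = field(default_factory=dict)
    scale_lambda: float = 0.0
    raw_library_sizes: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input_genes": self.n_input_genes,
            "n_expressed_all_replicates": self.n_expressed_all_replicates,
            "n_unexpressed": self.n_unexpressed,
            "n_partial_removed": self.n_partial_removed,
            "n_partial_kept": self.n_partial_kept,
            "n_constant_removed": self.n_constant_removed,
            "n_lowcpm_removed": self.n_lowcpm_removed,
            "n_retained": self.n_retained,
            "deg_loss_percent": self.deg_loss_percent,
            "scale_lambda": self.scale_lambda,
            "size_factors": self.size_factors,
            "raw_library_sizes": self.raw_library_sizes,
            "removed_ids": self.removed_ids,
        }


def scale_correct(matrix: CountMatrix) -> tuple[CountMatrix, float, np.ndarray]:
    """Rescale every library to the smallest library total.

    Returns the corrected matrix (``is_raw=False``), the common total
    ``lambda`` and the original column sums ``nu``.
    """
    nu = matrix.values.sum(axis=0)
    zero = np.flatnonzero(nu == 0)
    if zero.size:
        raise MixedDEError(
            f"library {matrix.samples[zero[0]]!r} has zero total count"
        )
    lam = float(nu.min())
    corrected = matrix.values * (lam / nu)
    out = CountMatrix(
        list(matrix.genes), list(matrix.samples), corrected, is_raw=False
    )
    return out, lam, nu


def rle_size_factors(matrix: CountMatrix) -> np.ndarray:
    """Median-of-ratios (relative log expression) per-sample size factors.

    The reference is the per-gene geometric mean across samples, computed
    over genes with strictly positive counts in every sample; each sample's
    factor is the median ratio of its counts to the reference.
    """
    vals = matrix.values
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise MixedDEError(
            "RLE undefined: no gene has positive counts in all samples"
        )
    ref = vals[allpos]
    geomean = np.exp(np.log(ref).mean(axis=1))
    sf = np.median(ref / geomean[:, None], axis=0)
    return sf


def normalize_rle(matrix: CountMatrix) -> tuple[CountMatrix, np.ndarray]:
    """Divide each column by its RLE size factor."""
    sf = rle_size_factors(matrix)
    out = CountMatrix(
        list(matrix.genes), list(matrix.samples), matrix.values / sf, is_raw=False
    )
    return out, sf


@lru_cache(maxsize=100_000)
def _exact_ranksum_p(key: tuple[int, ...]) -> float:
    """Exact two-sided rank-sum p for a count vector vs. equal-length zeros.

    ``key`` is the sorted tuple of counts. The null enumerates all equally
    likely assignments of the pooled 2n values into two groups of n; ties
    are handled through midranks. Enumeration is a subset-sum dynamic
    program over doubled midranks (integers).
    """
    y = np.array(key, dtype=float)
    n = y.size
    pooled = np.concatenate([y, np.zeros(n)])
    ranks = scipy.stats.rankdata(pooled)
    dr = np.round(2 * ranks).astype(int)
    obs = int(dr[:n].sum())
    total = int(dr.sum())
    mu2 = total * n / (2 * n)  # expected doubled rank sum of one group
    # f[k][s] = number of size-k subsets of dr with doubled-rank sum s
    maxs = total
    f = np.zeros((n + 1, maxs + 1), dtype=np.int64)
    f[0, 0] = 1
    for r in dr:
        for k in range(min(n, 1_000), 0, -1):
            f[k, r:] += f[k - 1, : maxs + 1 - r]
    dev = abs(obs - mu2)
    sums = np.arange(maxs + 1)
    hits = f[n, np.abs(sums - mu2) >= dev - 1e-9].sum()
    return float(hits / comb(2 * n, n))


def ranksum_vs_zero_p(counts: np.ndarray) -> float:
    """Two-sided rank-sum p-value of a count vector against all zeros.

    Exact enumeration for pooled group size up to ``EXACT_RANKSUM_MAX_N``;
    tie-corrected normal approximation above.
    """
    y = np.asarray(counts, dtype=float)
    n = y.size
    if n <= EXACT_RANKSUM_MAX_N:
        return _exact_ranksum_p(tuple(sorted(np.round(y).astype(int))))
    res = scipy.stats.mannwhitneyu(
        y, np.zeros(n), alternative="two-sided", method="asymptotic"
    )
    return float(res.pvalue)


def filter_all_zero(matrix: CountMatrix) -> tuple[CountMatrix, list[str]]:
    """Drop genes with zero reads in every sample."""
    keep = (matrix.values > 0).any(axis=1)
    removed = [g for g, k in zip(matrix.genes, keep) if not k]
    return matrix.subset_genes(keep), removed


def filter_partial_wilcoxon(
    matrix: CountMatrix, alpha: float = 0.05
) -> tuple[CountMatrix, list[str], list[str]]:
    """Test partially expressed genes against null counts; drop the
    indistinguishable ones.

    Only genes with at least one zero and one positive entry are tested;
    fully expressed genes bypass the test. A tested gene is kept iff its
    two-sided p-value is below ``alpha`` and is then grouped with the
    fully expressed genes.
    """
    vals = matrix.values
    has_zero = (vals == 0).any(axis=1)
    has_pos = (vals > 0).any(axis=1)
    partial = has_zero & has_pos
    keep = np.ones(matrix.n_genes, dtype=bool)
    kept_partial: list[str] = []
    removed: list[str] = []
    for i in np.flatnonzero(partial):
        p = ranksum_vs_zero_p(vals[i])
        if p < alpha:
            kept_partial.append(matrix.genes[i])
        else:
            keep[i] = False
            removed.append(matrix.genes[i])
    return matrix.subset_genes(keep), removed, kept_partial


def filter_constant(matrix: CountMatrix) -> tuple[CountMatrix, list[str]]:
    """Drop genes whose read count is identical in every sample."""
    vals = matrix.values
    keep = (vals != vals[:, [0]]).any(axis=1)
    removed = [g for g, k in zip(matrix.genes, keep) if not k]
    return matrix.subset_genes(keep), removed


def filter_low_cpm(
    matrix: CountMatrix,
    raw_library_sizes: np.ndarray,
    threshold: float = 1.0,
) -> tuple[CountMatrix, list[str]]:
    """Drop genes whose mean counts-per-million is at or below ``threshold``.

    CPM is computed against the raw (pre-correction) library sizes.
    """
    libs = np.asarray(raw_library_sizes, dtype=float)
    if (libs <= 0).any():
        raise MixedDEError("raw library sizes must be positive")
    cpm = matrix.values / libs * 1e6
    keep = cpm.mean(axis=1) > threshold
    removed = [g for g, k in zip(matrix.genes, keep) if not k]
    return matrix.subset_genes(keep), removed


def preprocess(
    matrix: CountMatrix,
    design: DesignTable | None = None,
    config: PreprocessConfig | None = None,
    truth_deg: dict[str, bool] | None = None,
) -> tuple[CountMatrix, PreprocessReport]:
    """Run the full preprocessing pipeline.

    Returns the normalized matrix restricted to retained genes, plus a
    report whose stage tallies partition the input gene count. Filters are
    decided on the raw counts (equality and zero patterns are only
    meaningful there); the returned values are scale-corrected and
    RLE-normalized. ``truth_deg`` maps gene id -> is-DEG and, when given,
    fills ``deg_loss_percent`` (percent of true DEGs removed).
    """
    config = config or PreprocessConfig()
    if design is not None and list(matrix.samples) != list(design.sample_ids):
        raise MixedDEError("matrix and design are not aligned")

    report = PreprocessReport(n_input_genes=matrix.n_genes)
    raw_libs = matrix.values.sum(axis=0)
    report.raw_library_sizes = {
        s: float(v) for s, v in zip(matrix.samples, raw_libs)
    }

    norm = matrix
    if config.run_scale_correction:
        norm, lam, _ = scale_correct(norm)
        report.scale_lambda = lam
    if config.run_rle:
        norm, sf = normalize_rle(norm)
        report.size_factors = {s: float(v) for s, v in zip(matrix.samples, sf)}

    raw = matrix
    report.n_expressed_all_replicates = int((raw.values > 0).all(axis=1).sum())

    stage1, rm_zero = filter_all_zero(raw)
    stage2, rm_partial, kept_partial = filter_partial_wilcoxon(
        stage1, config.wilcoxon_alpha
    )
    stage3, rm_const = filter_constant(stage2)
    stage4, rm_low = filter_low_cpm(stage3, raw_libs, config.cpm_threshold)

    report.n_unexpressed = len(rm_zero)
    report.n_partial_removed = len(rm_partial)
    report.n_partial_kept = len(kept_partial)
    report.n_constant_removed = len(rm_const)
    report.n_lowcpm_removed = len(rm_low)
    report.n_retained = stage4.n_genes
    report.removed_ids = {
        "all_zero": rm_zero,
        "wilcoxon": rm_partial,
        "constant": rm_const,
        "low_cpm": rm_low,
    }
    report.retained_ids = list(stage4.genes)

    if truth_deg is not None:
        n_deg = sum(bool(truth_deg.get(g, False)) for g in matrix.genes)
        retained = set(stage4.genes)
        lost = sum(
            bool(truth_deg.get(g, False))
            for g in matrix.genes
            if g not in retained
        )
        report.deg_loss_percent = 100.0 * lost / n_deg if n_deg else 0.0

    out = norm.subset_genes(stage4.genes)
    return out, report
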