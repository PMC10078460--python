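"""Differential-expression inference over a whole count matrix.

`DEAnalysis` is the top-level model object: construct it from a raw count
matrix plus a design table, call :meth:`DEAnalysis.fit`, and receive a
:class:`DEResults` carrying one row per retained gene with the condition
log2 fold change, average logCPM, Wald statistic, raw and adjusted
p-values and the up/down/ns call.

Normalization enters the per-gene NB models as a log offset,
``log(size_factor_j * raw_library_j)``, so the likelihood still sees
integer counts while coefficients are comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from . import glmm
from .data import CountMatrix, DesignTable, MixedDEError, align
from .dispersion import classify_matrix
from .preprocess import PreprocessConfig, PreprocessReport, preprocess, rle_size_factors


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg or Bonferroni adjusted p-values.

    NaNs are passed through and excluded from the effective test count m.
    Input order is preserved; BH applies the step-up cumulative minimum
    and caps at 1.
    """
    p = np.asarray(p, dtype=float)
    finite = p[np.isfinite(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise MixedDEError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return q
    if method.upper() in ("BONFERRONI", "BON"):
        q[ok] = np.minimum(1.0, p[ok] * m)
        return q
    if method.upper() != "BH":
        raise MixedDEError(f"unknown correction {method!r}")
    pv = p[ok]
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def average_logcpm(y: np.ndarray, raw_library_sizes: np.ndarray) -> float:
    """Mean over samples of log2(CPM + 0.5), on raw library sizes."""
    cpm = np.asarray(y, float) / np.asarray(raw_library_sizes, float) * 1e6
    return float(np.log2(cpm + 0.5).mean())


def classify_direction(
    log2fc: float, q: float, alpha: float, lfc_cutoff: float
) -> str:
    if not np.isfinite(q) or q >= alpha:
        return "ns"
    if log2fc >= lfc_cutoff:
        return "up"
    if log2fc <= -lfc_cutoff:
        return "down"
    return "ns"


def summarize_gene(
    fit: glmm.NBGLMMResults,
    y: np.ndarray,
    raw_library_sizes: np.ndarray,
    alpha_fdr: float = 0.05,
    lfc_cutoff: float = 0.0,
    q_value: float | None = None,
) -> dict:
    """Per-gene result row from a converged fit.

    When ``q_value`` is None the raw p stands in (single-gene use).
    """
    stat, p = glmm.wald_test(fit)
    log2fc = fit.log2fc
    q = p if q_value is None else q_value
    return {
        "log2fc": log2fc,
        "avg_logcpm": average_logcpm(y, raw_library_sizes),
        "wald_stat": stat,
        "p_value": p,
        "q_value": q,
        "direction": classify_direction(log2fc, q, alpha_fdr, lfc_cutoff),
    }


RESULT_COLUMNS = [
    "log2fc", "avg_logcpm", "wald_stat", "p_value", "q_value",
    "direction", "converged", "boundary", "theta", "sigma2",
]


def run_inference(
    matrix: CountMatrix,
    design: DesignTable,
    random_col: str | None = None,
    correction: str = "BH",
    alpha: float = 0.05,
    lfc_cutoff: float = 0.0,
    size_factors: np.ndarray | None = None,
    raw_library_sizes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit the per-gene NB (mixed) model to every gene of a raw matrix.

    ``matrix`` should hold raw counts of the genes retained by
    preprocessing; size factors and raw library sizes default to values
    recomputed from the matrix itself. Deterministic: no randomness in
    fitting, fixed initializations.
    """
    if matrix.n_genes == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    if list(matrix.samples) != list(design.sample_ids):
        raise MixedDEError("matrix and design are not aligned")
    libs = (
        matrix.values.sum(axis=0)
        if raw_library_sizes is None
        else np.asarray(raw_library_sizes, float)
    )
    if size_factors is None:
        try:
            size_factors = rle_size_factors(matrix)
        except MixedDEError:
            size_factors = np.ones(matrix.n_samples)
    sf = np.asarray(size_factors, float)
    offset = np.log(sf * libs)
    offset = offset - offset.mean()

    cond = design.condition_indicator.astype(float)
    groups = design.random_groups[random_col] if random_col else None
    out = glmm.fit_matrix(matrix.values, cond, groups=groups, offset=offset)

    beta1 = out[:, 1]
    se1 = out[:, 3]
    converged = out[:, 7] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(converged & (se1 > 0), beta1 / se1, np.nan)
    df = max(matrix.n_samples - 2, 1)
    p = np.where(
        np.isfinite(stat), 2.0 * scipy.stats.t.sf(np.abs(stat), df=df), np.nan
    )
    q = adjust_pvalues(p, correction)
    log2fc = beta1 / np.log(2.0)
    cpm = matrix.values / libs * 1e6
    avg_logcpm = np.log2(cpm + 0.5).mean(axis=1)
    direction = np.where(
        np.isfinite(q) & (q < alpha),
        np.where(log2fc >= lfc_cutoff, "up",
                 np.where(log2fc <= -lfc_cutoff, "down", "ns")),
        "ns",
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "avg_logcpm": avg_logcpm,
            "wald_stat": stat,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "converged": converged,
            "boundary": out[:, 8] > 0,
            "theta": out[:, 4],
            "sigma2": out[:, 5],
        },
        index=pd.Index(matrix.genes, name="gene_id"),
    )


def run_inference_glm(
    matrix: CountMatrix,
    design: DesignTable,
    correction: str = "BH",
    alpha: float = 0.05,
    lfc_cutoff: float = 0.0,
    size_factors: np.ndarray | None = None,
    raw_library_sizes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fixed-effects-only counterpart of :func:`run_inference`.

    The NB GLM baseline the mixed model is benchmarked against: the same
    adjusted-profile estimation path with the random intercept disabled,
    so that any benchmark difference reflects the random effect and not
    a calibration mismatch between fitting routes.
    """
    return run_inference(
        matrix, design, random_col=None, correction=correction, alpha=alpha,
        lfc_cutoff=lfc_cutoff, size_factors=size_factors,
        raw_library_sizes=raw_library_sizes,
    )


@dataclass
class DEResults:
    """Results of a full differential-expression run."""

    results: pd.DataFrame
    report: PreprocessReport
    correction: str
    alpha: float
    lfc_cutoff: float
    random_col: str | None = None

    @property
    def degs(self) -> pd.DataFrame:
        """Significant genes (direction up or down)."""
        return self.results[self.results["direction"] != "ns"]

    def summary(self) -> str:
        r = self.results
        n_up = int((r["direction"] == "up").sum())
        n_down = int((r["direction"] == "down").sum())
        lines = [
            "Differential expression (NB mixed model, Wald test)",
            f"  correction={self.correction}  alpha={self.alpha}  "
            f"lfc_cutoff={self.lfc_cutoff}  random={self.random_col or 'none'}",
            f"  input genes       {self.report.n_input_genes}",
            f"  retained genes    {self.report.n_retained}",
            f"  fitted genes      {len(r)}  "
            f"(non-converged {int((~r['converged']).sum())})",
            f"  DEGs              {n_up + n_down}  (up {n_up}, down {n_down})",
        ]
        top = r[r["direction"] != "ns"].nsmallest(10, "q_value")
        if len(top):
            lines.append("  top genes by q-value:")
            for g, row in top.iterrows():
                lines.append(
                    f"    {g:<16} log2fc={row['log2fc']: .3f} "
                    f"q={row['q_value']:.3g} {row['direction']}"
                )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.results.to_csv(path, sep="\t")


class DEAnalysis:
    """Top-level model: raw counts + design -> fitted DE results.

    Runs preprocessing (scale correction, RLE, expression filters), then
    fits the per-gene NB mixed model with the condition fixed effect and
    an optional random intercept, and assembles the gene result table.
    """

    def __init__(
        self,
        counts: CountMatrix,
        design: DesignTable,
        preprocess_config: PreprocessConfig | None = None,
    ):
        self.counts, self.design = align(counts, design)
        self.preprocess_config = preprocess_config or PreprocessConfig()

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        design: pd.DataFrame,
        condition: str,
        random: list[str] | str | None = None,
        **kwargs,
    ) -> "DEAnalysis":
        """Build from pandas objects (genes x samples; design indexed or
        with a sample_id column)."""
        cm = CountMatrix.from_frame(counts)
        if "sample_id" in design.columns:
            sids = list(design["sample_id"].astype(str))
        else:
            sids = [str(s) for s in design.index]
        random = [random] if isinstance(random, str) else (random or [])
        dt = DesignTable(
            sids,
            list(design[condition].astype(str)),
            {c: list(design[c].astype(str)) for c in random},
            condition_name=condition,
        )
        return cls(cm, dt, **kwargs)

    def fit(
        self,
        random_col: str | None = None,
        correction: str = "BH",
        alpha: float = 0.05,
        lfc_cutoff: float = 0.0,
        overdispersed_only: bool = False,
        truth_deg: dict[str, bool] | None = None,
    ) -> DEResults:
        cols = list(self.design.random_groups)
        if random_col is None and len(cols) == 1:
            random_col = cols[0]
        if random_col is not None and random_col not in self.design.random_groups:
            raise MixedDEError(f"unknown random column {random_col!r}")

        _, report = preprocess(
            self.counts, self.design, self.preprocess_config, truth_deg
        )
        retained_raw = self.counts.subset_genes(report.retained_ids)

        if overdispersed_only and retained_raw.n_genes:
            summ = classify_matrix(retained_raw, self.design)
            keep = summ.labels == "overdispersed"
            retained_raw = retained_raw.subset_genes(keep)

        libs = np.array(
            [report.raw_library_sizes[s] for s in self.counts.samples]
        )
        sf = (
            np.array([report.size_factors[s] for s in self.counts.samples])
            if report.size_factors
            else None
        )
        table = run_inference(
            retained_raw,
            self.design,
            random_col=random_col,
            correction=correction,
            alpha=alpha,
            lfc_cutoff=lfc_cutoff,
            size_factors=sf,
            raw_library_sizes=libs,
        )
        return DEResults(
            results=table,
            report=report,
            correction=correction,
            alpha=alpha,
            lfc_cutoff=lfc_cutoff,
            random_col=random_col,
        )
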