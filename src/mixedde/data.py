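"""Core containers and I/O for count matrices and sample design tables.

A :class:`CountMatrix` is a gene-by-sample table of non-negative read
counts (raw integers straight from a counter, or real-valued after scale
correction / normalization).  A :class:`DesignTable` carries per-sample
metadata: the two-level experimental condition plus zero or more
categorical grouping columns used as random effects (e.g. gender,
individual).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class MixedDEError(ValueError):
    """Base class for input validation failures."""


@dataclass
class CountMatrix:
    """Gene-by-sample count table.

    Parameters
    ----------
    genes : list of str
        Unique gene identifiers (row labels).
    samples : list of str
        Unique sample identifiers (column labels).
    values : ndarray, shape (n_genes, n_samples)
        Non-negative counts. Integers when ``is_raw`` is true.
    is_raw : bool
        True for unnormalized integer read counts.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    is_raw: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.values.shape if self.values.ndim == 2 else (0, 0)
        if self.values.ndim != 2:
            raise MixedDEError("count matrix must be 2-dimensional")
        if len(self.genes) != m or len(self.samples) != n:
            raise MixedDEError(
                f"label/shape mismatch: {len(self.genes)} genes, "
                f"{len(self.samples)} samples, values {self.values.shape}"
            )
        if n < 2:
            raise MixedDEError("need at least 2 samples")
        dup_g = _duplicates(self.genes)
        if dup_g:
            raise MixedDEError(f"duplicate gene ids: {sorted(dup_g)}")
        dup_s = _duplicates(self.samples)
        if dup_s:
            raise MixedDEError(f"duplicate sample ids: {sorted(dup_s)}")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise MixedDEError(
                f"negative count at gene {self.genes[i]!r}, "
                f"sample {self.samples[j]!r}: {self.values[i, j]}"
            )
        if self.is_raw and not np.allclose(self.values, np.round(self.values)):
            warnings.warn(
                "raw count matrix contains non-integer entries; the model "
                "expects unnormalized read counts",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def subset_genes(self, keep: np.ndarray | list) -> "CountMatrix":
        """Row-subset by boolean mask or list of gene ids (order preserved)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.genes)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        return CountMatrix(
            [self.genes[i] for i in idx],
            list(self.samples),
            self.values[idx],
            is_raw=self.is_raw,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, is_raw: bool = True) -> "CountMatrix":
        return cls(
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
            df.to_numpy(dtype=float),
            is_raw=is_raw,
        )


@dataclass
class DesignTable:
    """Per-sample experimental design.

    ``condition`` must have exactly two observed levels in pairwise mode;
    the reference level is the first level in order of appearance, and the
    fitted condition coefficient is level2 minus level1 on the log scale.
    """

    sample_ids: list[str]
    condition: list[str]
    random_groups: dict[str, list[str]] = field(default_factory=dict)
    condition_name: str = "condition"

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise MixedDEError("duplicate sample ids in design")
        levels = list(dict.fromkeys(self.condition))
        if len(levels) != 2:
            raise MixedDEError(
                f"pairwise mode requires exactly 2 condition levels, "
                f"got {len(levels)}: {levels}"
            )
        counts = {lv: self.condition.count(lv) for lv in levels}
        low = [lv for lv, c in counts.items() if c < 2]
        if low:
            raise MixedDEError(
                f"each condition needs >= 2 biological replicates; "
                f"level(s) {low} have fewer"
            )
        for col, vals in self.random_groups.items():
            if len(vals) != len(self.sample_ids):
                raise MixedDEError(f"random column {col!r} length mismatch")

    @property
    def levels(self) -> list[str]:
        """Condition levels in order of first appearance (reference first)."""
        return list(dict.fromkeys(self.condition))

    @property
    def condition_indicator(self) -> np.ndarray:
        """0/1 vector: 1 where the sample is in the non-reference level."""
        ref = self.levels[0]
        return np.array([0 if c == ref else 1 for c in self.condition])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_codes(self, column: str) -> tuple[np.ndarray, list[str]]:
        """Integer codes and level list for a random grouping column."""
        vals = self.random_groups[column]
        levels = list(dict.fromkeys(vals))
        pos = {v: i for i, v in enumerate(levels)}
        return np.array([pos[v] for v in vals], dtype=np.int64), levels

    def subset(self, sample_ids: list[str]) -> "DesignTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return DesignTable(
            [self.sample_ids[i] for i in idx],
            [self.condition[i] for i in idx],
            {c: [v[i] for i in idx] for c, v in self.random_groups.items()},
            condition_name=self.condition_name,
        )


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def _infer_sep(path: Path, fmt: str | None) -> str:
    if fmt == "csv" or (fmt is None and path.suffix.lower() == ".csv"):
        return ","
    return "\t"


def read_counts(path: str | Path, fmt: str | None = None) -> CountMatrix:
    """Read a raw count matrix from TSV/CSV (genes x samples) or MatrixMarket.

    TSV/CSV: first column holds gene ids, header row holds sample ids.
    MatrixMarket (``.mtx``): coordinate file with ``genes.txt`` and
    ``samples.txt`` sidecars (one id per line) in the same directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "mtx" or (fmt is None and path.suffix.lower() == ".mtx"):
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = (path.parent / "genes.txt").read_text().split()
        samples = (path.parent / "samples.txt").read_text().split()
        return CountMatrix(genes, samples, np.asarray(mat, dtype=float))
    sep = _infer_sep(path, fmt)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 1:
        raise MixedDEError(f"malformed header in {path}: no sample columns")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MixedDEError(f"non-numeric entries in {path}: {exc}") from exc
    return CountMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], values
    )


def write_counts(matrix: CountMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write a count matrix as TSV/CSV or MatrixMarket with id sidecars."""
    path = Path(path)
    if fmt == "mtx" or (fmt is None and path.suffix.lower() == ".mtx"):
        vals = matrix.values
        ivals = np.round(vals).astype(np.int64)
        if np.allclose(vals, ivals):
            vals = ivals
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(vals))
        (path.parent / "genes.txt").write_text("\n".join(matrix.genes) + "\n")
        (path.parent / "samples.txt").write_text("\n".join(matrix.samples) + "\n")
        return
    sep = _infer_sep(path, fmt)
    df = matrix.to_frame()
    if matrix.is_raw:
        df = df.astype(np.int64)
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep)


def read_design(
    path: str | Path,
    condition_col: str,
    random_cols: list[str] | None = None,
    sample_col: str = "sample_id",
) -> DesignTable:
    """Read a per-sample design table from TSV/CSV.

    Categorical levels are recorded in order of first appearance; the first
    condition level seen is the reference for the fitted contrast.
    """
    path = Path(path)
    sep = _infer_sep(path, None)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in [sample_col, condition_col, *(random_cols or [])]:
        if col not in df.columns:
            raise MixedDEError(f"design file missing column {col!r}")
    return DesignTable(
        list(df[sample_col]),
        list(df[condition_col]),
        {c: list(df[c]) for c in (random_cols or [])},
        condition_name=condition_col,
    )


def align(matrix: CountMatrix, design: DesignTable) -> tuple[CountMatrix, DesignTable]:
    """Reorder matrix columns to the design row order; validate coverage.

    Idempotent: aligning already-aligned inputs returns equal objects.
    """
    pos = {s: i for i, s in enumerate(matrix.samples)}
    missing = [s for s in design.sample_ids if s not in pos]
    if missing:
        raise MixedDEError(f"design samples absent from count matrix: {missing}")
    uncovered = [s for s in matrix.samples if s not in set(design.sample_ids)]
    if uncovered:
        raise MixedDEError(f"matrix samples absent from design: {uncovered}")
    idx = [pos[s] for s in design.sample_ids]
    out = CountMatrix(
        list(matrix.genes),
        [matrix.samples[i] for i in idx],
        matrix.values[:, idx],
        is_raw=matrix.is_raw,
    )
    return out, design
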