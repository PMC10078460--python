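"""Scoring DEG calls against simulation truth, and the benchmark grid.

Genes removed by preprocessing are scored as negative calls — they can no
longer be detected, so true DEGs lost to filtering surface as false
negatives and penalize recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountMatrix, DesignTable, MixedDEError
from .inference import run_inference, run_inference_glm
from .preprocess import PreprocessConfig, preprocess
from .simulate import (
    RandomEffectConfig,
    SimConfig,
    SimResult,
    default_random_effect_mean,
    inject_random_effects,
    simulate_fixed,
)

log = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(truth: dict[str, bool], calls) -> ConfusionCounts:
    """Confusion counts over the simulated gene universe.

    ``truth`` maps gene id -> is-DEG. ``calls`` is either a set of called
    gene ids (everything else counts negative) or a dict gene id -> bool
    over exactly the same universe.
    """
    if isinstance(calls, dict):
        sym = set(truth) ^ set(calls)
        if sym:
            raise MixedDEError(
                f"truth and calls gene sets differ by {len(sym)} genes"
            )
        called = {g for g, v in calls.items() if v}
    else:
        called = set(calls)
        extra = called - set(truth)
        if extra:
            raise MixedDEError(
                f"calls contain {len(extra)} genes outside the truth universe"
            )
    tp = fp = tn = fn = 0
    for g, is_deg in truth.items():
        if g in called:
            if is_deg:
                tp += 1
            else:
                fp += 1
        else:
            if is_deg:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, accuracy).

    Corner cases: with no positive calls, precision is 1 when there was
    nothing to find (fn == 0) and 0 otherwise; recall with no true DEGs
    is 1.
    """
    if c.tp + c.fp == 0:
        precision = 1.0 if c.fn == 0 else 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    recall = 1.0 if c.tp + c.fn == 0 else c.tp / (c.tp + c.fn)
    accuracy = (c.tp + c.tn) / c.total if c.total else 1.0
    return precision, recall, accuracy


def call_degs(
    matrix: CountMatrix,
    design: DesignTable,
    engine: str = "mixedde",
    correction: str = "BH",
    alpha: float = 0.05,
    lfc_cutoff: float = 0.0,
    random_col: str | None = "sample",
    config: PreprocessConfig | None = None,
) -> set[str]:
    """Preprocess a raw matrix and return the set of genes called DEG.

    ``engine`` is "mixedde" (NB GLMM with a random intercept over
    ``random_col``) or "glm" (fixed-effects NB GLM baseline).
    """
    _, report = preprocess(matrix, design, config)
    retained = matrix.subset_genes(report.retained_ids)
    libs = np.array([report.raw_library_sizes[s] for s in matrix.samples])
    sf = (
        np.array([report.size_factors[s] for s in matrix.samples])
        if report.size_factors
        else None
    )
    if engine == "mixedde":
        table = run_inference(
            retained, design, random_col=random_col, correction=correction,
            alpha=alpha, lfc_cutoff=lfc_cutoff, size_factors=sf,
            raw_library_sizes=libs,
        )
    elif engine == "glm":
        table = run_inference_glm(
            retained, design, correction=correction, alpha=alpha,
            lfc_cutoff=lfc_cutoff, size_factors=sf, raw_library_sizes=libs,
        )
    else:
        raise MixedDEError(f"unknown engine {engine!r}")
    if not len(table):
        return set()
    return set(table.index[table["direction"] != "ns"])


def score_calls(truth: dict[str, str], called: set[str]) -> dict:
    """Precision/recall/accuracy of a call set against labeled truth."""
    truth_bool = {g: lab != "non-DEG" for g, lab in truth.items()}
    c = confusion(truth_bool, called)
    precision, recall, accuracy = metrics(c)
    return {
        "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
        "precision": precision, "recall": recall, "accuracy": accuracy,
    }


def read_external_calls(path) -> set[str]:
    """Two-column TSV (gene_id, yes/no or true/false) from any caller."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    gid, flag = df.columns[:2]
    yes = {"yes", "true", "1", "y"}
    return {
        str(g) for g, v in zip(df[gid], df[flag])
        if str(v).strip().lower() in yes
    }


def benchmark_grid(
    cells: list[dict],
    methods: list[str],
    seeds: list[int],
    alpha: float = 0.05,
    lfc_cutoff: float = 0.0,
) -> pd.DataFrame:
    """Run the simulation benchmark over a grid of conditions.

    Each cell is a dict of :class:`SimConfig` overrides plus an optional
    ``sdnd`` (0 means fixed effects only; the injection mean defaults by
    replicate count). ``methods`` are "<engine>-<correction>" labels,
    e.g. ``mixedde-BH``, ``glm-BON``. One output row per
    (cell, method, seed); method failures yield NA metrics and the run
    continues.
    """
    rows = []
    for cell in cells:
        cell = dict(cell)
        sdnd = float(cell.pop("sdnd", 0))
        for seed in seeds:
            sim = simulate_fixed(SimConfig(seed=seed, **cell))
            matrix = sim.matrix
            if sdnd > 0:
                matrix = inject_random_effects(
                    matrix,
                    RandomEffectConfig(
                        sdnd=sdnd,
                        mean=default_random_effect_mean(sim.config.replicates),
                        seed=seed,
                    ),
                )
            for method in methods:
                engine, _, corr = method.rpartition("-")
                row = {
                    "replicates": sim.config.replicates,
                    "deg_proportion": sim.config.deg_proportion,
                    "sdnd": sdnd,
                    "method": method,
                    "correction": corr,
                    "seed": seed,
                }
                try:
                    called = call_degs(
                        matrix, sim.design, engine=engine, correction=corr,
                        alpha=alpha, lfc_cutoff=lfc_cutoff,
                    )
                    row.update(score_calls(sim.truth, called))
                except Exception as exc:  # scored NA, run continues
                    log.warning("method %s failed on cell %s: %s", method, cell, exc)
                    row.update({k: np.nan for k in
                                ("tp", "fp", "tn", "fn",
                                 "precision", "recall", "accuracy")})
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of accuracy (and means of precision/recall) per method."""
    return table.groupby("method").agg(
        precision=("precision", "mean"),
        recall=("recall", "mean"),
        accuracy_mean=("accuracy", "mean"),
        accuracy_sd=("accuracy", "std"),
        n_runs=("accuracy", "size"),
    )
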