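"""Synthetic RNA-seq count matrices with known differential expression.

`simulate_fixed` emulates a two-condition bulk RNA-seq experiment with
only fixed effects: expressed genes draw NB2 counts around log-normal
baseline means, a configurable share of genes is differentially expressed
at a 1:1 up:down ratio, and structural gene classes (all-zero, partially
expressed, constant-count, low-CPM) are mixed in at fractions chosen so
that the preprocessing filters all have realistic work to do.

`inject_random_effects` degrades such a matrix with per-entry normal
perturbations (mean from the replicate-count defaults estimated on public
data, standard deviation the SDND), clamping negatives to zero and
rounding to the nearest integer — emulating strong between-individual
variability on top of the fixed effects.

Randomness uses counter-based Philox streams keyed per gene, so the same
seed reproduces the same matrix and row subsets keep their draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CountMatrix, DesignTable, MixedDEError

#: per-replicate-count default means of the injected normal perturbation,
#: estimated from public two-condition expression datasets
RANDOM_EFFECT_MEANS = {
    2: 2.028, 3: 9.937, 4: 7.158,
    5: -3.429, 6: -3.429, 7: -3.429, 8: -3.429, 9: -3.429,
    10: -1.615, 15: -1.615,
}

SDND_CHOICES = (100, 300, 600, 900, 1200, 2000, 3000)


def default_random_effect_mean(replicates: int) -> float:
    """Default injection mean for a given per-condition replicate count."""
    if replicates in RANDOM_EFFECT_MEANS:
        return RANDOM_EFFECT_MEANS[replicates]
    if 5 <= replicates <= 9:
        return RANDOM_EFFECT_MEANS[5]
    if replicates >= 10:
        return RANDOM_EFFECT_MEANS[10]
    raise MixedDEError(f"no default mean for {replicates} replicates")


@dataclass
class SimConfig:
    """Fixed-effect simulation parameters.

    Structural fractions partition the transcriptome the way observed
    bulk matrices do: roughly a third of annotated genes never expressed,
    a tenth sporadically expressed, a sliver constant, a fifth below the
    CPM floor, the rest cleanly expressed.
    """

    n_genes: int = 38_293
    replicates: int = 6
    deg_proportion: float = 0.10
    baseline_log_mean: float = float(np.log(500.0))
    baseline_log_sd: float = 1.5
    nb_dispersion: float = 0.09
    #: weakly/sporadically expressed genes are noisier than the core
    #: (mean-dispersion trend of real data); their zeros arise naturally
    partial_log_mean: float = float(np.log(2.5))
    partial_log_sd: float = 0.7
    structural_dispersion: float = 0.49
    lfc_low: float = 1.0
    lfc_high: float = 2.0
    f_all_zero: float = 0.34
    f_partial: float = 0.10
    f_constant: float = 0.001
    f_low: float = 0.22
    #: share of DEG labels falling in the partial / low-CPM classes,
    #: reproducing the observed few-percent DEG loss through filtering
    deg_share_partial: float = 0.02
    deg_share_low: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise MixedDEError("n_genes must be >= 10")
        if not 2 <= self.replicates <= 15:
            raise MixedDEError("replicates per condition must be in 2..15")
        if not 0 <= self.deg_proportion <= 1:
            raise MixedDEError("deg_proportion must be in [0, 1]")
        fr = self.f_all_zero + self.f_partial + self.f_constant + self.f_low
        bad = [
            f for f in (self.f_all_zero, self.f_partial, self.f_constant, self.f_low)
            if not 0 <= f <= 1
        ]
        if bad or fr >= 1:
            raise MixedDEError("structural fractions must be in [0,1] and sum < 1")
        if self.nb_dispersion < 0:
            raise MixedDEError("nb_dispersion must be >= 0")


@dataclass
class RandomEffectConfig:
    """Normal perturbation added entrywise to a fixed-effect matrix."""

    sdnd: float
    mean: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sdnd < 0:
            raise MixedDEError("sdnd must be >= 0")


@dataclass
class SimResult:
    matrix: CountMatrix
    truth: dict[str, str]  # gene_id -> "non-DEG" | "up" | "down"
    design: DesignTable
    config: SimConfig = field(repr=False)

    @property
    def truth_deg(self) -> dict[str, bool]:
        return {g: lab != "non-DEG" for g, lab in self.truth.items()}


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[seed, index]))


def _nb_draw(rng, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB2 counts via the gamma-Poisson mixture; Poisson when phi == 0."""
    mean = np.maximum(mean, 1e-12)
    if phi <= 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    return rng.poisson(rng.gamma(shape, mean * phi))


def simulate_fixed(config: SimConfig) -> SimResult:
    """Simulate a two-condition raw count matrix with known DEGs."""
    m = config.n_genes
    r = config.replicates
    n = 2 * r
    master = _gene_rng(config.seed, 2**32)

    n_zero = round(config.f_all_zero * m)
    n_partial = round(config.f_partial * m)
    n_const = round(config.f_constant * m)
    n_low = round(config.f_low * m)
    n_core = m - n_zero - n_partial - n_const - n_low

    # class id per gene: 0 core, 1 all-zero, 2 partial, 3 constant, 4 low
    classes = np.repeat(
        np.array([0, 1, 2, 3, 4]),
        [n_core, n_zero, n_partial, n_const, n_low],
    )
    master.shuffle(classes)

    half = round(m * config.deg_proportion / 2)
    n_deg = 2 * half
    n_deg_partial = min(round(config.deg_share_partial * n_deg), n_partial)
    n_deg_low = min(round(config.deg_share_low * n_deg), n_low)
    n_deg_core = n_deg - n_deg_partial - n_deg_low
    if n_deg_core > n_core:
        raise MixedDEError("not enough expressed genes for requested DEGs")

    deg_idx = np.concatenate([
        master.choice(np.flatnonzero(classes == 0), n_deg_core, replace=False),
        master.choice(np.flatnonzero(classes == 2), n_deg_partial, replace=False),
        master.choice(np.flatnonzero(classes == 4), n_deg_low, replace=False),
    ]).astype(int)
    master.shuffle(deg_idx)
    sign = np.zeros(m, dtype=int)
    sign[deg_idx[:half]] = 1
    sign[deg_idx[half:]] = -1

    # per-gene baseline means (condition 1)
    lam = np.zeros(m)
    core_or_partial = (classes == 0) | (classes == 2)
    lam[classes == 0] = master.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, n_core
    )
    lam[classes == 2] = master.lognormal(
        config.partial_log_mean, config.partial_log_sd, n_partial
    )
    const_vals = master.integers(1, 101, n_const)
    # expected per-sample library from the informative classes
    l0 = lam[core_or_partial].sum() + const_vals.sum()
    lam[classes == 4] = master.uniform(0.1, 0.8, n_low) * max(l0, 1.0) / 1e6
    lfc = master.uniform(config.lfc_low, config.lfc_high, m)

    values = np.zeros((m, n), dtype=np.int64)
    const_pos = np.flatnonzero(classes == 3)
    const_map = {int(i): int(v) for i, v in zip(const_pos, const_vals)}
    for i in range(m):
        cls = classes[i]
        if cls == 1:
            continue
        if cls == 3:
            values[i, :] = const_map[i]
            continue
        rng = _gene_rng(config.seed, i)
        phi = config.nb_dispersion if cls == 0 else config.structural_dispersion
        mu1 = lam[i]
        mu2 = mu1 * 2.0 ** (sign[i] * lfc[i]) if sign[i] else mu1
        mean = np.concatenate([np.full(r, mu1), np.full(r, mu2)])
        values[i, :] = _nb_draw(rng, mean, phi)

    genes = [f"gene_{i + 1:06d}" for i in range(m)]
    samples = [f"A_r{j + 1}" for j in range(r)] + [f"B_r{j + 1}" for j in range(r)]
    cond = ["A"] * r + ["B"] * r
    matrix = CountMatrix(genes, samples, values.astype(float), is_raw=True)
    design = DesignTable(samples, cond, {"sample": list(samples)})
    label = np.where(sign == 1, "up", np.where(sign == -1, "down", "non-DEG"))
    truth = {g: str(lab) for g, lab in zip(genes, label)}
    return SimResult(matrix=matrix, truth=truth, design=design, config=config)


def estimate_random_effect_mean(matrix: CountMatrix, design: DesignTable) -> float:
    """Mean parameter for injection, estimated from a (preprocessed)
    two-condition matrix: the average over genes of (condition-2 replicate
    mean minus condition-1 replicate mean)."""
    cond = design.condition_indicator
    if len(set(cond.tolist())) < 2:
        raise MixedDEError("need two conditions")
    m2 = matrix.values[:, cond == 1].mean(axis=1)
    m1 = matrix.values[:, cond == 0].mean(axis=1)
    return float((m2 - m1).mean())


def inject_random_effects(
    matrix: CountMatrix, re_config: RandomEffectConfig
) -> CountMatrix:
    """Add one N(mean, sdnd^2) draw to every entry; clamp negatives to
    zero and round half-away-from-zero to the nearest integer."""
    mean = re_config.mean
    if mean is None:
        mean = default_random_effect_mean(matrix.n_samples // 2)
    rng = _gene_rng(re_config.seed, 2**33)
    noise = rng.normal(mean, re_config.sdnd, size=matrix.values.shape)
    out = np.maximum(matrix.values + noise, 0.0)
    out = np.floor(out + 0.5)  # half-away-from-zero for non-negative values
    return CountMatrix(
        list(matrix.genes), list(matrix.samples), out, is_raw=True
    )
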