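import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mixedde import (
    CountMatrix,
    DesignTable,
    MixedDEError,
    PreprocessConfig,
    filter_all_zero,
    filter_constant,
    filter_low_cpm,
    filter_partial_wilcoxon,
    preprocess,
    rle_size_factors,
    scale_correct,
)
from mixedde.preprocess import ranksum_vs_zero_p


def _cm(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    genes = [f"{prefix}{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(genes, samples, values)


class TestScaleCorrect:
    def test_hand_example(self):
        out, lam, nu = scale_correct(_cm([[10, 30], [10, 10]]))
        assert lam == 20
        np.testing.assert_array_equal(nu, [20, 40])
        np.testing.assert_allclose(out.values, [[10, 15], [10, 5]])
        assert not out.is_raw

    def test_equal_libraries_unchanged(self):
        m = _cm([[5, 5], [10, 10]])
        out, _, _ = scale_correct(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_zero_library_named(self):
        with pytest.raises(MixedDEError, match="s1"):
            scale_correct(_cm([[1, 0], [2, 0]]))

    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(2, 12), st.integers(2, 6)),
            elements=st.integers(0, 500).map(float),
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_column_sums_equal_lambda(self, values):
        if (values.sum(axis=0) == 0).any():
            return
        out, lam, _ = scale_correct(_cm(values))
        np.testing.assert_allclose(
            out.values.sum(axis=0), lam, rtol=1e-9
        )

    def test_doubling_non_minimal_library_keeps_its_corrected_column(self):
        vals = np.array([[10.0, 30.0], [10.0, 10.0]])
        base, lam0, _ = scale_correct(_cm(vals))
        doubled = vals.copy()
        doubled[:, 1] *= 2  # library 2 is not the minimum; lambda unchanged
        out, lam1, _ = scale_correct(_cm(doubled))
        assert lam0 == lam1
        np.testing.assert_allclose(out.values[:, 1], base.values[:, 1])


class TestRLE:
    def test_hand_example(self):
        sf = rle_size_factors(_cm([[4, 16], [1, 4]]))
        np.testing.assert_allclose(sf, [0.5, 2.0])

    def test_identical_columns_give_unit_factors(self):
        sf = rle_size_factors(_cm([[7, 7, 7], [3, 3, 3]]))
        np.testing.assert_allclose(sf, [1, 1, 1])

    def test_column_scaling_scales_factor_ratios(self):
        # the geometric-mean reference shifts by c**(1/n) too, so the
        # invariant forced by the formula is on size-factor ratios
        base = np.array([[4.0, 8.0], [10.0, 20.0], [6.0, 12.0]])
        sf0 = rle_size_factors(_cm(base))
        scaled = base.copy()
        scaled[:, 0] *= 3
        sf1 = rle_size_factors(_cm(scaled))
        np.testing.assert_allclose(sf1[0] / sf1[1], 3 * sf0[0] / sf0[1])

    def test_requires_one_all_positive_gene(self):
        with pytest.raises(MixedDEError, match="RLE"):
            rle_size_factors(_cm([[0, 1], [1, 0]]))


def brute_force_ranksum_p(counts):
    """Independent oracle: enumerate every assignment of the pooled
    values into two equal groups and count rank sums at least as extreme."""
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    pooled = np.concatenate([counts, np.zeros(n)])
    ranks = scipy.stats.rankdata(pooled)
    obs = ranks[:n].sum()
    mu = ranks.sum() / 2
    hits = 0
    total = 0
    for idx in itertools.combinations(range(2 * n), n):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mu) >= abs(obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestRanksumVsZero:
    @pytest.mark.parametrize(
        "counts",
        [
            (0, 0, 0, 5),
            (0, 1, 2, 3),
            (0, 8, 9, 7, 0, 6),
            (0, 0, 1, 1, 2, 2),
            (0, 5, 5, 5, 5, 5, 5, 0),
        ],
    )
    def test_matches_exhaustive_enumeration(self, counts):
        assert ranksum_vs_zero_p(np.array(counts)) == pytest.approx(
            brute_force_ranksum_p(counts)
        )

    def test_clearly_expressed_gene_is_significant(self):
        p = ranksum_vs_zero_p(np.array([0, 8, 9, 10, 7, 0, 6, 5, 9, 8]))
        assert p < 0.05

    def test_single_positive_count_is_not_significant(self):
        assert ranksum_vs_zero_p(np.array([0, 0, 0, 5])) > 0.05


class TestFilters:
    def test_all_zero(self):
        m = _cm([[0, 0, 0, 0], [0, 0, 0, 1]])
        out, removed = filter_all_zero(m)
        assert removed == ["g0"]
        assert out.genes == ["g1"]

    def test_all_zero_no_op(self):
        m = _cm([[1, 0], [2, 3]])
        out, removed = filter_all_zero(m)
        assert removed == [] and out.genes == m.genes

    def test_partial_wilcoxon_keeps_expressed_and_tests_partial(self):
        full = [5, 8, 9, 10, 7, 9, 6, 5, 9, 8]
        strong_partial = [0, 8, 9, 10, 7, 0, 6, 5, 9, 8]
        weak_partial = [0, 0, 0, 0, 0, 0, 0, 0, 0, 5]
        m = _cm([full, strong_partial, weak_partial])
        out, removed, kept = filter_partial_wilcoxon(m, alpha=0.05)
        assert removed == ["g2"]
        assert kept == ["g1"]
        assert out.genes == ["g0", "g1"]

    def test_constant(self):
        m = _cm([[7, 7, 7, 7], [7, 7, 7, 8]])
        out, removed = filter_constant(m)
        assert removed == ["g0"]
        assert out.genes == ["g1"]

    def test_low_cpm_hand_examples(self):
        m = _cm([[1, 1], [6, 6]])
        libs = np.array([2e6, 2e6])
        out, removed = filter_low_cpm(m, libs, threshold=1.0)
        # gene 0: CPM (0.5, 0.5), mean 0.5 <= 1 -> removed
        # gene 1: CPM (3, 3), mean 3 > 1 -> kept
        assert removed == ["g0"]
        assert out.genes == ["g1"]

    def test_low_cpm_threshold_zero_keeps_positive_genes(self):
        m = _cm([[1, 0]])
        out, removed = filter_low_cpm(m, np.array([1e6, 1e6]), threshold=0.0)
        assert removed == [] and out.genes == ["g0"]


class TestPreprocessPipeline:
    def _fixture(self):
        # 6 genes: one all-zero, one constant, one low-CPM, three clean
        values = np.array(
            [
                [0, 0, 0, 0],
                [9, 9, 9, 9],
                [1, 2, 1, 1],
                [100_000, 120_000, 110_000, 130_000],
                [240_000, 220_000, 200_000, 260_000],
                [1_660_000, 1_660_000, 1_690_000, 1_610_000],
            ],
            dtype=float,
        )
        # gene "low" has mean CPM ~0.6 against ~2e6-read libraries
        genes = ["zero", "const", "low", "a", "b", "c"]
        cm = CountMatrix(genes, ["s1", "s2", "s3", "s4"], values)
        design = DesignTable(["s1", "s2", "s3", "s4"], ["A", "A", "B", "B"])
        return cm, design

    def test_six_gene_fixture_partition(self):
        cm, design = self._fixture()
        out, report = preprocess(cm, design)
        assert report.n_retained == 3
        assert set(report.retained_ids) == {"a", "b", "c"}
        assert report.removed_ids["all_zero"] == ["zero"]
        assert report.removed_ids["constant"] == ["const"]
        assert report.removed_ids["low_cpm"] == ["low"]
        total_removed = sum(len(v) for v in report.removed_ids.values())
        assert report.n_retained + total_removed == report.n_input_genes

    def test_truth_all_non_deg_gives_zero_loss(self):
        cm, design = self._fixture()
        _, report = preprocess(cm, design, truth_deg={g: False for g in cm.genes})
        assert report.deg_loss_percent == 0.0

    def test_deg_loss_counts_removed_true_degs(self):
        cm, design = self._fixture()
        truth = {g: g in {"low", "a"} for g in cm.genes}
        _, report = preprocess(cm, design, truth_deg=truth)
        assert report.deg_loss_percent == pytest.approx(50.0)

    def test_no_removals_returns_normalized_input(self):
        values = np.array(
            [[10, 20, 30, 40], [40, 30, 20, 10], [25, 25, 25, 26]], dtype=float
        )
        cm = _cm(values)
        out, report = preprocess(cm)
        assert report.n_retained == 3
        assert out.genes == cm.genes
        # scale-corrected columns all sum to the minimum library
        np.testing.assert_allclose(
            (out.values * np.array(list(report.size_factors.values()))).sum(axis=0),
            report.scale_lambda,
            rtol=1e-9,
        )

    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(3, 25), st.integers(4, 8)),
            elements=st.integers(0, 60).map(float),
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_tallies_always_partition_input(self, values):
        if (values.sum(axis=0) == 0).any() or not (values > 0).all(axis=1).any():
            return
        cm = _cm(values)
        out, report = preprocess(cm)
        total_removed = sum(len(v) for v in report.removed_ids.values())
        assert report.n_retained + total_removed == report.n_input_genes
        removed_sets = [set(v) for v in report.removed_ids.values()]
        for i in range(len(removed_sets)):
            for j in range(i + 1, len(removed_sets)):
                assert not removed_sets[i] & removed_sets[j]
        # filtering only deletes rows of the normalized matrix
        assert set(out.genes) <= set(cm.genes)

    def test_config_validation(self):
        with pytest.raises(MixedDEError):
            PreprocessConfig(wilcoxon_alpha=1.5)
        with pytest.raises(MixedDEError):
            PreprocessConfig(cpm_threshold=-1)
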