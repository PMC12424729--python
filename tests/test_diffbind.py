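"""The NB differential-binding engine against hand and simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleaid.diffbind import (
    ALPHA_MIN,
    CountMatrix,
    bh_adjust,
    count_fragments,
    estimate_dispersion,
    estimate_size_factors,
    merge_union,
    wald_contrast,
)
from nucleaid.exceptions import DataError
from nucleaid.intervals import GenomicInterval, PeakSet
from nucleaid.simulate import _nb_draw


def make_cm(counts: np.ndarray, conditions, features=None) -> CountMatrix:
    samples = pd.DataFrame(
        {"condition": conditions, "replicate": list(range(1, len(conditions) + 1))},
        index=pd.Index([f"s{i}" for i in range(len(conditions))], name="sample"),
    )
    idx = features or [f"f{i}" for i in range(counts.shape[0])]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(idx, name="feature"), columns=samples.index),
        samples=samples,
    )


def simulated_cm(rng, n_peaks, mu, alpha, lfc=0.0, reps=2, size_factors=None):
    """Two-condition NB matrix with a planted B-over-A log2 fold change."""
    mu = np.broadcast_to(np.asarray(mu, float), (n_peaks,))
    alpha = np.broadcast_to(np.asarray(alpha, float), (n_peaks,))
    conditions = ["A"] * reps + ["B"] * reps
    s = np.ones(2 * reps) if size_factors is None else np.asarray(size_factors)
    cols = []
    for j, cond in enumerate(conditions):
        m = mu * (2.0**lfc if cond == "B" else 1.0) * s[j]
        cols.append(_nb_draw(rng, m, alpha))
    cm = make_cm(np.column_stack(cols), conditions)
    cm.size_factors = pd.Series(s, index=cm.counts.columns)
    return cm


class TestMergeUnion:
    def test_overlapping_merged(self):
        a = PeakSet([GenomicInterval("chr1", 100, 200, "x")])
        b = PeakSet([GenomicInterval("chr1", 150, 250, "y")])
        union = merge_union([a, b])
        assert [(i.start, i.end) for i in union] == [(100, 250)]
        assert union.sources[union.names[0]] == ["x", "y"]

    def test_book_ended_merged(self):
        a = PeakSet([GenomicInterval("chr1", 100, 200, "x"), GenomicInterval("chr1", 200, 300, "y")])
        union = merge_union([a])
        assert [(i.start, i.end) for i in union] == [(100, 300)]

    def test_different_chromosomes_retained(self):
        a = PeakSet([GenomicInterval("chr1", 100, 200, "x")])
        b = PeakSet([GenomicInterval("chr2", 100, 200, "x")])
        assert len(merge_union([a, b])) == 2

    def test_empty_input_error(self):
        with pytest.raises(DataError):
            merge_union([])


class TestCountFragments:
    def test_overlap_and_spanning_fragment(self):
        union = merge_union(
            [PeakSet([GenomicInterval("chr1", 100, 200, "p1"), GenomicInterval("chr1", 250, 350, "p2")])]
        )
        frags = PeakSet(
            [
                GenomicInterval("chr1", 150, 160, "a"),  # inside p1
                GenomicInterval("chr1", 190, 260, "b"),  # spans p1 and p2
            ]
        )
        cm = count_fragments(union, {"s1": frags})
        assert cm.counts["s1"].tolist() == [2, 1]

    def test_zero_fragments_zero_column(self):
        union = merge_union([PeakSet([GenomicInterval("chr1", 0, 10, "p")])])
        cm = count_fragments(union, {"s1": PeakSet([GenomicInterval("chr2", 0, 5, "f")])})
        assert cm.counts["s1"].tolist() == [0]


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_cm(np.array([[10, 10], [7, 7]]), ["A", "B"])
        estimate_size_factors(cm)
        np.testing.assert_allclose(cm.size_factors.values, [1.0, 1.0])

    def test_scale_equivariance(self):
        cm = make_cm(np.array([[10, 20], [50, 100], [7, 14]]), ["A", "B"])
        estimate_size_factors(cm)
        sA, sB = cm.size_factors
        assert sB / sA == pytest.approx(2.0)

    def test_worked_three_feature_grid(self):
        """Hand computation: geometric means (sqrt(200), sqrt(20000),
        sqrt(32)); every ratio in column A is 1/sqrt(2) -> s = (1/sqrt 2, sqrt 2)."""
        cm = make_cm(np.array([[10, 20], [100, 200], [4, 8]]), ["A", "B"])
        estimate_size_factors(cm)
        np.testing.assert_allclose(
            cm.size_factors.values, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_no_all_positive_feature_error(self):
        cm = make_cm(np.array([[0, 5], [3, 0]]), ["A", "B"])
        with pytest.raises(DataError, match="size factors"):
            estimate_size_factors(cm)


class TestDispersion:
    def test_poisson_data_floored_near_alpha_min(self):
        rng = np.random.default_rng(0)
        cm = simulated_cm(rng, 400, mu=100.0, alpha=0.0, reps=250)
        alpha = estimate_dispersion(cm)
        assert np.median(alpha) < 2e-3  # Var ~ mean: MoM excess is noise-level

    def test_nb_consistency_alpha_point_two(self):
        rng = np.random.default_rng(1)
        cm = simulated_cm(rng, 300, mu=200.0, alpha=0.2, reps=100)
        alpha = estimate_dispersion(cm)
        assert 0.1 <= np.median(alpha) <= 0.3

    def test_constant_counts_floored(self):
        cm = make_cm(np.full((3, 4), 9), ["A", "A", "B", "B"])
        estimate_size_factors(cm)
        alpha = estimate_dispersion(cm)
        np.testing.assert_allclose(alpha.values, ALPHA_MIN)


class TestBHAdjust:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_hand_written_step_up(self, ps):
        """Oracle: sort, p_(i) * m / i, cumulative min from the right."""
        m = len(ps)
        order = np.argsort(ps, kind="mergesort")
        adj_sorted = np.minimum.accumulate(
            (np.array(ps)[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        expect = np.minimum(1.0, np.empty(m))
        expect[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(ps), expect, rtol=1e-12, atol=1e-15)


class TestWaldContrast:
    def test_identical_groups_null(self):
        cm = make_cm(np.array([[50, 50, 50, 50], [9, 9, 9, 9]]), ["A", "A", "B", "B"])
        estimate_size_factors(cm)
        res = wald_contrast(cm, "A", "B")
        np.testing.assert_allclose(res.table["log2FoldChange"], 0.0)
        np.testing.assert_allclose(res.table["pvalue"], 1.0)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        cm = simulated_cm(rng, 50, mu=300.0, alpha=0.05, lfc=1.0)
        ab = wald_contrast(cm, "A", "B")
        ba = wald_contrast(cm, "B", "A")
        np.testing.assert_allclose(
            ab.table["log2FoldChange"], -ba.table["log2FoldChange"], rtol=1e-12
        )
        np.testing.assert_allclose(ab.table["pvalue"], ba.table["pvalue"], rtol=1e-12)

    def test_unknown_condition_error(self):
        cm = make_cm(np.array([[1, 2]]), ["A", "B"])
        cm.size_factors = pd.Series([1.0, 1.0], index=cm.counts.columns)
        with pytest.raises(DataError, match="condition"):
            wald_contrast(cm, "A", "C")

    def test_planted_lfc_recovered(self):
        """Parameter recovery: planted log2FC = -3, mu = 500, alpha = 0.05,
        n = 2 per group, 1,000 peaks -> mean estimate within 0.15 of -3."""
        rng = np.random.default_rng(3)
        cm = simulated_cm(rng, 1000, mu=500.0, alpha=0.05, lfc=-3.0)
        res = wald_contrast(cm, "A", "B")
        assert abs(res.table["log2FoldChange"].mean() - (-3.0)) < 0.15

    def test_padj_never_below_p(self):
        rng = np.random.default_rng(4)
        cm = simulated_cm(rng, 200, mu=100.0, alpha=0.05, lfc=0.5)
        t = wald_contrast(cm, "A", "B").table
        assert (t["padj"] >= t["pvalue"] - 1e-15).all()
        assert t["padj"].between(0, 1).all()

    def test_scale_invariance(self):
        """Scaling one sample's counts by c while scaling its size factor by
        c leaves the contrast unchanged."""
        rng = np.random.default_rng(5)
        cm = simulated_cm(rng, 80, mu=200.0, alpha=0.05, lfc=1.0)
        base = wald_contrast(cm, "A", "B").table
        scaled_counts = cm.counts.copy()
        scaled_counts.iloc[:, 0] *= 3
        cm2 = CountMatrix(counts=scaled_counts, samples=cm.samples)
        sf = cm.size_factors.copy()
        sf.iloc[0] *= 3
        cm2.size_factors = sf
        scaled = wald_contrast(cm2, "A", "B").table
        pd.testing.assert_frame_equal(base, scaled, rtol=1e-9)


class TestErrorRates:
    def test_type_i_error_under_null(self):
        """With no planted effect the double threshold (|lfc| > 1.5 and
        padj < 0.005) fires on < 0.5% of 2,000 peaks."""
        rng = np.random.default_rng(6)
        cm = simulated_cm(
            rng, 2000, mu=rng.lognormal(np.log(500), 0.5, 2000), alpha=0.05, lfc=0.0
        )
        res = wald_contrast(cm, "A", "B")
        frac = res.significant(1.5, 0.005).mean()
        assert frac < 0.005

    def test_power_on_planted_effects(self):
        """Planted |log2FC| = 3 at mu >= 100, alpha <= 0.1, n = 2 per group
        is detected at both thresholds for >= 95% of peaks."""
        rng = np.random.default_rng(7)
        mu = rng.uniform(100, 1000, 1000)
        alpha = rng.uniform(0.01, 0.1, 1000)
        cm = simulated_cm(rng, 1000, mu=mu, alpha=alpha, lfc=-3.0)
        res = wald_contrast(cm, "A", "B")
        assert res.significant(1.5, 0.005, sign=-1).mean() >= 0.95
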