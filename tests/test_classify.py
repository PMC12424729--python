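"""Dual-contrast peak classification, widths, distances and annotation."""

import numpy as np
import pandas as pd
import pytest

from nucleaid.classify import (
    ClassifierThresholds,
    annotate_genomic_context,
    classify,
    flag_presence,
    interpeak_distances,
    nearest_gene,
    width_stats,
)
from nucleaid.diffbind import ContrastResult
from nucleaid.exceptions import DataError
from nucleaid.intervals import GenomicInterval, PeakSet
from nucleaid.io import GeneModel


def contrast(features, lfc, padj, a="A", b="B") -> ContrastResult:
    lfc = np.asarray(lfc, float)
    padj = np.asarray(padj, float)
    return ContrastResult(
        condition_a=a,
        condition_b=b,
        table=pd.DataFrame(
            {
                "baseMean": 100.0,
                "log2FoldChange": lfc,
                "lfcSE": 0.1,
                "dispersion": 0.05,
                "pvalue": padj,
                "padj": padj,
            },
            index=pd.Index(features, name="feature"),
        ),
    )


def presence_frame(features, ss, aux, re):
    return pd.DataFrame(
        {
            "present_steady_state": ss,
            "present_auxin": aux,
            "present_reintroduction": re,
        },
        index=pd.Index(features, name="feature"),
    )


class TestFlagPresence:
    def setup_method(self):
        self.union = PeakSet([GenomicInterval("chr1", 100, 200, "u0"), GenomicInterval("chr1", 500, 600, "u1")])

    def test_presence_per_condition(self):
        calls = {
            "steady_state": PeakSet([GenomicInterval("chr1", 150, 300, "a")]),
            "auxin": PeakSet([GenomicInterval("chr2", 0, 50, "b")]),
            "reintroduction": PeakSet([GenomicInterval("chr1", 599, 700, "c")]),
        }
        pf = flag_presence(self.union, calls)
        assert pf.loc["u0"].tolist() == [True, False, False]
        assert pf.loc["u1"].tolist() == [False, False, True]  # 1-bp overlap counts

    def test_missing_condition_error(self):
        with pytest.raises(DataError, match="auxin"):
            flag_presence(
                self.union,
                {
                    "steady_state": PeakSet([]),
                    "reintroduction": PeakSet([]),
                },
            )


class TestClassify:
    def one_peak(self, lfc1, padj1, lfc2, padj2, ss=True, aux=False, re=True):
        pres = presence_frame(["u0"], [ss], [aux], [re])
        c1 = contrast(["u0"], [lfc1], [padj1])
        c2 = contrast(["u0"], [lfc2], [padj2])
        return classify(pres, c1, c2).table.loc["u0", "label"]

    def test_nucleation_quadrant(self):
        assert self.one_peak(-3.0, 1e-6, 2.5, 1e-5) == "nucleation"

    def test_boundary_lfc_strict(self):
        assert self.one_peak(-1.5, 1e-6, 2.5, 1e-5) != "nucleation"

    def test_boundary_padj_strict(self):
        assert self.one_peak(-3.0, 0.005, 2.5, 1e-5) != "nucleation"

    def test_persistent_requires_auxin_presence(self):
        assert self.one_peak(-0.1, 0.9, 0.1, 0.9, aux=True) == "persistent"
        assert self.one_peak(-0.1, 0.9, 0.1, 0.9, aux=False) == "control_exclusive"

    def test_new_classes_excluded_from_nucleation(self):
        # present only in auxin: bookkept as new, never nucleation
        assert self.one_peak(-3.0, 1e-6, 2.5, 1e-5, ss=False, aux=True) == "new_in_auxin"
        assert self.one_peak(-3.0, 1e-6, 2.5, 1e-5, ss=False, aux=False, re=True) == "new_in_reintro"

    def test_absent_everywhere_excluded(self):
        assert self.one_peak(0.0, 1.0, 0.0, 1.0, ss=False, aux=False, re=False) == "excluded"

    def test_feature_mismatch_error(self):
        pres = presence_frame(["u0"], [True], [False], [True])
        c1 = contrast(["u0"], [-3], [1e-6])
        c2 = contrast(["OTHER"], [3], [1e-6])
        with pytest.raises(DataError, match="union"):
            classify(pres, c1, c2)

    def test_partition_every_peak_exactly_one_label(self):
        rng = np.random.default_rng(0)
        n = 500
        feats = [f"u{i}" for i in range(n)]
        pres = presence_frame(
            feats, rng.random(n) < 0.7, rng.random(n) < 0.3, rng.random(n) < 0.5
        )
        c1 = contrast(feats, rng.normal(0, 3, n), rng.random(n))
        c2 = contrast(feats, rng.normal(0, 3, n), rng.random(n))
        cls = classify(pres, c1, c2)
        assert sum(cls.class_sizes().values()) == n

    def test_threshold_monotonicity(self):
        """Raising lfc_min or lowering padj_max never adds nucleation calls."""
        rng = np.random.default_rng(1)
        n = 400
        feats = [f"u{i}" for i in range(n)]
        pres = presence_frame(feats, [True] * n, [False] * n, [True] * n)
        c1 = contrast(feats, rng.normal(-2, 1.5, n), rng.random(n) * 0.02)
        c2 = contrast(feats, rng.normal(2, 1.5, n), rng.random(n) * 0.02)
        base = classify(pres, c1, c2).class_sizes()["nucleation"]
        stricter_lfc = classify(
            pres, c1, c2, ClassifierThresholds(lfc_min=2.5, padj_max=0.005)
        ).class_sizes()["nucleation"]
        stricter_p = classify(
            pres, c1, c2, ClassifierThresholds(lfc_min=1.5, padj_max=0.001)
        ).class_sizes()["nucleation"]
        assert stricter_lfc <= base and stricter_p <= base


class TestWidthStats:
    def test_median_of_three(self):
        union = PeakSet(
            [
                GenomicInterval("chr1", 0, 100, "a"),
                GenomicInterval("chr1", 200, 400, "b"),
                GenomicInterval("chr1", 500, 800, "c"),
            ]
        )
        pres = presence_frame(["a", "b", "c"], [True] * 3, [False] * 3, [True] * 3)
        c1 = contrast(["a", "b", "c"], [-3] * 3, [1e-6] * 3)
        c2 = contrast(["a", "b", "c"], [3] * 3, [1e-6] * 3)
        cls = classify(pres, c1, c2)
        ws = width_stats(cls, union)
        assert ws.loc["nucleation", "n"] == 3
        assert ws.loc["nucleation", "median"] == 200
        assert ws.loc["persistent", "n"] == 0 and np.isnan(ws.loc["persistent", "median"])


class TestInterpeakDistances:
    def test_pairwise_gap(self):
        ps = PeakSet([GenomicInterval("chr1", 100, 200, "a"), GenomicInterval("chr1", 500, 600, "b")])
        d = interpeak_distances(ps)
        assert d.loc["a"] == 300 and d.loc["b"] == 300

    def test_overlapping_pair_zero(self):
        ps = PeakSet([GenomicInterval("chr1", 100, 200, "a"), GenomicInterval("chr1", 150, 300, "b")])
        assert (interpeak_distances(ps) == 0).all()

    def test_nearest_not_consecutive(self):
        # c's nearest left neighbour by edge gap is the long peak a, not b
        ps = PeakSet(
            [
                GenomicInterval("chr1", 0, 1000, "a"),
                GenomicInterval("chr1", 10, 20, "b"),
                GenomicInterval("chr1", 1100, 1200, "c"),
            ]
        )
        assert interpeak_distances(ps).loc["c"] == 100

    def test_sole_peak_on_chromosome_nan(self):
        ps = PeakSet(
            [
                GenomicInterval("chr1", 0, 10, "a"),
                GenomicInterval("chr1", 50, 60, "b"),
                GenomicInterval("chr2", 0, 10, "c"),
            ]
        )
        d = interpeak_distances(ps)
        assert np.isnan(d.loc["c"]) and d.loc["a"] == 40

    def test_all_singletons_error(self):
        ps = PeakSet([GenomicInterval("chr1", 0, 10, "a"), GenomicInterval("chr2", 0, 10, "b")])
        with pytest.raises(DataError):
            interpeak_distances(ps)

    def test_fewer_than_two_error(self):
        with pytest.raises(DataError):
            interpeak_distances(PeakSet([GenomicInterval("chr1", 0, 10, "a")]))


GENES = [
    GeneModel("geneB", "chr1", 10_000, GenomicInterval("chr1", 10_000, 30_000), "+", ((10_000, 11_000), (25_000, 26_000))),
    GeneModel("geneA", "chr1", 50_000, GenomicInterval("chr1", 40_001, 50_001), "-", ()),
]


class TestAnnotation:
    def peak(self, mid, name="p"):
        return PeakSet([GenomicInterval("chr1", mid - 5, mid + 5, name)])

    def test_upstream_of_tss_is_promoter(self):
        assert annotate_genomic_context(self.peak(9_500), GENES).iloc[0] == "promoter"

    def test_exon_and_intron(self):
        assert annotate_genomic_context(self.peak(25_500), GENES).iloc[0] == "exon"
        assert annotate_genomic_context(self.peak(20_000), GENES).iloc[0] == "intron"

    def test_intergenic(self):
        assert annotate_genomic_context(self.peak(35_000), GENES).iloc[0] == "intergenic"


class TestNearestGene:
    def test_midpoint_at_tss_distance_zero(self):
        out = nearest_gene(self.peak_at(10_000), GENES)
        assert out.iloc[0]["gene_id"] == "geneB" and out.iloc[0]["distance"] == 0

    def test_equidistant_tie_lexicographic(self):
        # midpoint 30,000: 20,000 from both TSSs -> geneA wins by name
        out = nearest_gene(self.peak_at(30_000), GENES)
        assert out.iloc[0]["gene_id"] == "geneA"

    def test_signed_distance_respects_strand(self):
        # 1 kb before the minus-strand TSS (genomically) is downstream
        out = nearest_gene(self.peak_at(49_000), GENES)
        assert out.iloc[0]["gene_id"] == "geneA" and out.iloc[0]["distance"] == 1000

    def test_chromosome_without_genes_missing(self):
        ps = PeakSet([GenomicInterval("chr9", 0, 10, "p")])
        out = nearest_gene(ps, GENES)
        assert out.iloc[0]["gene_id"] is None

    @staticmethod
    def peak_at(mid):
        return PeakSet([GenomicInterval("chr1", mid - 5, mid + 5, "p")])
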