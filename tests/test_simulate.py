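"""The synthetic-data generator: determinism and planted-structure recovery."""

import dataclasses

import numpy as np
import pytest

from nucleaid.exceptions import ConfigError, DataError
from nucleaid.loops import apa, classify_loop_anchors
from nucleaid.methylation import call_island_status, gc_content
from nucleaid.simulate import (
    SimConfig,
    _nb_draw,
    generate_bin_counts,
    generate_condition_calls,
    generate_counts,
    generate_genome,
    generate_loops_and_matrix,
    generate_methylation,
    generate_truth,
)


@pytest.fixture(scope="module")
def truth(small_sim_config):
    return generate_truth(small_sim_config)


class TestConfig:
    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, n_nucleation=-1)

    def test_resolution_must_divide_chromosome(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, chrom_length=1_234_567)


class TestTruthAndCounts:
    def test_class_counts_match_config(self, small_sim_config, truth):
        vc = truth.peaks["label"].value_counts().to_dict()
        for label, n in small_sim_config.class_counts().items():
            assert vc.get(label, 0) == n

    def test_peaks_non_overlapping_and_sorted(self, truth):
        for _, sub in truth.peaks.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()

    def test_same_seed_identical_counts(self, small_sim_config, truth):
        c1 = generate_counts(truth, small_sim_config)
        c2 = generate_counts(truth, small_sim_config)
        assert c1.counts.equals(c2.counts)

    def test_different_seed_differs(self, small_sim_config, truth):
        other = dataclasses.replace(small_sim_config, seed=99)
        assert not generate_counts(truth, small_sim_config).counts.equals(
            generate_counts(generate_truth(other), other).counts
        )

    def test_poisson_limit_mean(self):
        """alpha -> 0, s = 1: the sample mean of 10,000 draws is within 2%
        of the NB mean (Poisson limit)."""
        rng = np.random.default_rng(0)
        draws = _nb_draw(rng, np.full(10_000, 150.0), np.zeros(10_000))
        assert abs(draws.mean() / 150.0 - 1) < 0.02

    def test_planted_depletion_ratio(self, small_sim_config, truth):
        """Planted contrast-1 log2FC of -3 puts the auxin-condition mean at
        ~mu/8 for nucleation peaks (after removing size factors)."""
        cm = generate_counts(truth, small_sim_config)
        norm = cm.counts / truth.size_factors
        nuc = truth.peaks["label"] == "nucleation"
        ss_cols = [s for s in norm if s.startswith("steady_state")]
        aux_cols = [s for s in norm if s.startswith("auxin")]
        ratio = norm.loc[nuc.values, aux_cols].values.mean() / norm.loc[
            nuc.values, ss_cols
        ].values.mean()
        assert ratio == pytest.approx(1 / 8, rel=0.15)

    def test_calls_follow_planted_presence(self, small_sim_config, truth):
        calls = generate_condition_calls(truth, small_sim_config)
        nuc_names = set(truth.peaks.index[truth.peaks["label"] == "nucleation"])
        assert nuc_names <= set(calls["steady_state"].names)
        assert nuc_names.isdisjoint(calls["auxin"].names)
        assert nuc_names <= set(calls["reintroduction"].names)

    def test_bin_counts_recover_size_factors(self, small_sim_config, truth):
        from nucleaid.diffbind import estimate_size_factors

        bc = generate_bin_counts(truth, small_sim_config)
        estimate_size_factors(bc)
        ratio = bc.size_factors / truth.size_factors
        # size factors are relative (compare up to a common scale); the
        # small config has ~120 bins, so the median-of-ratios carries a
        # few percent of sampling noise
        np.testing.assert_allclose(ratio / ratio.mean(), 1.0, rtol=0.06)


class TestGenome:
    def test_background_gc_concentration(self):
        """On a 100 kb genome the non-island GC fraction concentrates
        within 0.42 +/- 0.03 (binomial bound)."""
        cfg = SimConfig(seed=5, n_chromosomes=1, chrom_length=100_000, n_cgi_random=1)
        seqs, cgis, _ = generate_genome(cfg)
        (chrom,) = seqs
        seq = seqs[chrom]
        mask = np.ones(len(seq), dtype=bool)
        for iv in cgis:
            mask[iv.start : iv.end] = False
        background = "".join(c for c, m in zip(seq, mask) if m)
        assert abs(gc_content(background) - 0.42) < 0.03

    def test_island_composition_contract(self, small_sim_config, truth):
        seqs, cgis, _ = generate_genome(small_sim_config, truth)
        for iv in list(cgis)[:25]:
            s = seqs[iv.chrom][iv.start : iv.end]
            assert gc_content(s) >= 0.65
            assert s.count("CG") / len(s) >= 0.06

    def test_deterministic_fasta(self, small_sim_config, truth):
        s1, _, _ = generate_genome(small_sim_config, truth)
        s2, _, _ = generate_genome(small_sim_config, truth)
        assert s1 == s2


class TestMethylation:
    def test_planted_island_status_round_trip(self, small_sim_config, truth):
        """Every planted island status is recovered by the caller."""
        seqs, cgis, cgi_truth = generate_genome(small_sim_config, truth)
        meth = generate_methylation(cgis, cgi_truth, seqs, small_sim_config)
        calls = call_island_status(cgis, meth)
        for call in calls:
            assert call.status == cgi_truth.loc[call.island.name, "planted_status"]


class TestLoopsAndMatrix:
    def test_counts_and_anchor_classes(self, small_sim_config, truth):
        loops, matrices = generate_loops_and_matrix(truth, small_sim_config)
        total = (
            small_sim_config.n_loops_zero
            + small_sim_config.n_loops_one
            + small_sim_config.n_loops_two
        )
        assert len(loops) == total
        out = classify_loop_anchors(loops, truth.peak_set("nucleation"))
        from collections import Counter

        counts = Counter(lp.n_nucleation_anchors for lp in out)
        assert counts[2] == small_sim_config.n_loops_two
        assert counts[1] == small_sim_config.n_loops_one
        assert counts[0] == small_sim_config.n_loops_zero

    def test_min_span_respected(self, small_sim_config, truth):
        loops, _ = generate_loops_and_matrix(truth, small_sim_config)
        min_bp = small_sim_config.min_loop_span_bins * small_sim_config.resolution
        assert all(lp.span >= min_bp for lp in loops)

    def test_loop_pixel_above_local_background(self, small_sim_config, truth):
        loops, matrices = generate_loops_and_matrix(truth, small_sim_config)
        lp = loops[0]
        m = matrices[lp.anchor1.chrom]
        b1 = m.bin_index(lp.anchor1.midpoint)
        b2 = m.bin_index(lp.anchor2.midpoint)
        assert m.values[b1, b2] > m.values[b1, b2 + 1]
        assert m.values[b1, b2] > m.values[b1 + 1, b2]

    def test_apa_recovers_planted_enrichment(self, small_sim_config, truth):
        loops, matrices = generate_loops_and_matrix(truth, small_sim_config)
        res = apa(loops, matrices, w=5)
        assert res.score > 1.0

    def test_zero_loops_pure_decay_apa_undefined(self, small_sim_config):
        cfg = dataclasses.replace(
            small_sim_config, n_loops_zero=0, n_loops_one=0, n_loops_two=0
        )
        truth0 = generate_truth(cfg)
        loops, matrices = generate_loops_and_matrix(truth0, cfg)
        assert loops == []
        with pytest.raises(DataError):
            apa(loops, matrices, w=5)
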