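"""Likelihood-driven copy-number/allelic-imbalance segmentation."""

import math

import numpy as np
import pytest

from um_landscape.segmentation import (GenomicSegment, LocusObservation,
                                       SegmentationParams, call_aberrations,
                                       normalize_copy_number,
                                       read_loci_tsv, segment_chromosome,
                                       segment_chromosome_with_trace,
                                       segments_to_frame,
                                       weighted_percentile_20)
from um_landscape import segmentation
from um_landscape.synth import SegmentSpec, simulate_cn_profile

from .oracles import best_single_split, exact_binom_two_sided


def make_segment(copy_number, maf, ai_p, chrom="chr3", start=1, end=1000,
                 label="neutral"):
    return GenomicSegment(chrom=chrom, start=start, end=end, n_loci=100,
                          copy_number=copy_number,
                          minor_allele_frequency=maf,
                          allelic_imbalance_p=ai_p, label=label)


class TestSegmentChromosome:
    def test_homogeneous_profile_is_one_segment(self):
        loci, _ = simulate_cn_profile([SegmentSpec(1000, 2.0, 0.5)], seed=0)
        segs = segment_chromosome(loci)
        assert len(segs) == 1
        assert segs[0].start == loci[0].pos and segs[0].end == loci[-1].pos
        assert sum(s.n_loci for s in segs) == 1000

    def test_step_profile_breakpoint_matches_exhaustive_scan(self):
        """A 1.0 -> 1.6 coverage-ratio step with tight noise: two segments,
        breakpoint within 10 loci of an exhaustive single-split scan."""
        rng = np.random.default_rng(3)
        loci = []
        for i in range(1000):
            ratio = 1.0 if i < 500 else 1.6
            loci.append(LocusObservation(
                chrom="chr8", pos=i + 1,
                tumor_coverage=float(rng.poisson(60 * ratio)),
                normal_coverage=float(rng.poisson(60))))
        segs, trace = segment_chromosome_with_trace(loci)
        assert len(segs) == 2
        found = trace[0].locus_index

        log_r = [math.log2((l.tumor_coverage + 0.5)
                           / (l.normal_coverage + 0.5)) for l in loci]

        def gaussian_ll(a, b):
            n = b - a
            mean = sum(log_r[a:b]) / n
            return -sum((x - mean) ** 2 for x in log_r[a:b])

        k_oracle, _ = best_single_split(loci, 10, gaussian_ll)
        assert abs(found - k_oracle) <= 10
        assert abs(found - 500) <= 10

    def test_small_ratio_step_below_gate_is_not_split(self):
        """A 5% coverage step stays one segment even with thousands of loci
        (LLR clears the bar but the 1.1 copy-ratio gate does not)."""
        rng = np.random.default_rng(4)
        loci = []
        for i in range(4000):
            ratio = 1.0 if i < 2000 else 1.05
            loci.append(LocusObservation(
                chrom="chr1", pos=i + 1,
                tumor_coverage=float(rng.poisson(200 * ratio)),
                normal_coverage=float(rng.poisson(200))))
        segs = segment_chromosome(loci)
        assert len(segs) == 1

    def test_planted_three_block_truth_recovered(self):
        layout = [SegmentSpec(400, 2.0, 0.5), SegmentSpec(400, 3.0, 1 / 3),
                  SegmentSpec(400, 1.0, 0.0)]
        loci, _ = simulate_cn_profile(layout, seed=12)
        segs, trace = segment_chromosome_with_trace(loci)
        found = sorted(r.locus_index for r in trace)
        for true_bp in (400, 800):
            assert any(abs(f - true_bp) <= 25 for f in found)
        assert all(r.llr > 90 for r in trace)

    def test_unsorted_input_rejected(self):
        loci = [LocusObservation("chr1", 10, 50, 50),
                LocusObservation("chr1", 5, 50, 50)]
        with pytest.raises(ValueError, match="sorted"):
            segment_chromosome(loci)

    def test_all_zero_normal_coverage_rejected(self):
        loci = [LocusObservation("chr1", i + 1, 50, 0) for i in range(30)]
        with pytest.raises(ValueError, match="normal coverage"):
            segment_chromosome(loci)

    def test_deterministic(self):
        loci, _ = simulate_cn_profile(
            [SegmentSpec(300, 2.0, 0.5), SegmentSpec(300, 1.0, 0.0)], seed=5)
        a = segments_to_frame(segment_chromosome(loci))
        b = segments_to_frame(segment_chromosome(loci))
        assert a.equals(b)


class TestAllelicImbalance:
    def test_exact_balance_not_flagged(self):
        assert segmentation.test_allelic_imbalance(500, 1000) > 0.9

    def test_imbalanced_pool_flagged(self):
        p = segmentation.test_allelic_imbalance(300, 1000)
        assert p < 0.001
        assert p == pytest.approx(exact_binom_two_sided(300, 1000),
                                  rel=1e-6)

    def test_single_small_locus_uninformative(self):
        assert segmentation.test_allelic_imbalance(3, 6) == pytest.approx(1.0)

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            segmentation.test_allelic_imbalance(0, 0)


class TestNormalization:
    def test_single_balanced_segment_anchors_to_two(self):
        segs = [make_segment(4.0, 0.5, 0.8)]
        normalized, factor = normalize_copy_number(segs)
        assert factor == pytest.approx(0.5)
        assert normalized[0].copy_number == pytest.approx(2.0)

    def test_weighted_percentile_anchors_on_largest_low_segment(self):
        segs = [
            make_segment(2.0, 0.5, 0.9, start=1, end=60_000_000),
            make_segment(3.0, 0.5, 0.9, start=60_000_001, end=90_000_000),
            make_segment(4.0, 0.5, 0.9, start=90_000_001, end=100_000_000),
        ]
        normalized, factor = normalize_copy_number(segs)
        # direct weighted-percentile computation: CDF hits 0.2 inside the
        # 60 Mb segment at copy 2.0
        values = np.array([2.0, 3.0, 4.0])
        weights = np.array([60e6, 30e6, 10e6])
        assert weighted_percentile_20(values, weights) == 2.0
        assert factor == pytest.approx(1.0)

    def test_homogeneity(self):
        segs = [make_segment(2.0, 0.5, 0.9), make_segment(3.0, 0.2, 0.5)]
        _, factor = normalize_copy_number(segs)
        scaled = [make_segment(s.copy_number * 2.5, s.minor_allele_frequency,
                               s.allelic_imbalance_p) for s in segs]
        _, factor_scaled = normalize_copy_number(scaled)
        assert factor_scaled == pytest.approx(factor / 2.5)

    def test_postcondition_holds_to_1e_9(self):
        rng = np.random.default_rng(8)
        segs = [make_segment(float(c), 0.5, 0.9, start=i * 1000 + 1,
                             end=(i + 1) * 1000)
                for i, c in enumerate(rng.uniform(1.5, 4.5, size=12))]
        normalized, _ = normalize_copy_number(segs)
        values = np.array([s.copy_number for s in normalized])
        weights = np.array([s.length for s in normalized], float)
        assert abs(weighted_percentile_20(values, weights) - 2.0) < 1e-9

    def test_no_balanced_segment_requires_manual_factor(self):
        segs = [make_segment(4.0, 0.1, 1e-6)]
        with pytest.raises(ValueError, match="manual"):
            normalize_copy_number(segs)
        normalized, factor = normalize_copy_number(segs, manual_factor=0.5)
        assert normalized[0].copy_number == pytest.approx(2.0)


class TestAberrationCalls:
    def test_monosomy_is_loss(self):
        labeled, _ = call_aberrations([make_segment(1.0, 0.0, 1e-9)])
        assert labeled[0].label == "loss"

    def test_copy_neutral_loh(self):
        labeled, _ = call_aberrations([make_segment(2.0, 0.02, 1e-6)])
        assert labeled[0].label == "cn_loh"

    def test_balanced_diploid_is_neutral(self):
        labeled, _ = call_aberrations([make_segment(2.0, 0.5, 0.9)])
        assert labeled[0].label == "neutral"

    def test_near_diploid_imbalance_above_loh_bound(self):
        labeled, _ = call_aberrations([make_segment(2.0, 0.2, 1e-6)])
        assert labeled[0].label == "imbalance_only"

    def test_arm_call_requires_80_percent_cover(self):
        arms = {"chr8": [("p", 1, 1000), ("q", 1001, 11000)]}
        segs = [make_segment(3.0, 0.33, 1e-6, chrom="chr8",
                             start=1001, end=10_000, label="gain"),
                make_segment(2.0, 0.5, 0.9, chrom="chr8",
                             start=10_001, end=11_000)]
        _, summary = call_aberrations(segs, arms=arms)
        q = summary[summary.arm == "q"].iloc[0]
        assert q.arm_call == "gain"
        p = summary[summary.arm == "p"].iloc[0]
        assert p.arm_call == "none"


class TestLociTsv:
    def test_round_trip(self, tmp_path):
        loci, _ = simulate_cn_profile([SegmentSpec(50, 2.0, 0.5)], seed=1)
        import pandas as pd
        path = tmp_path / "loci.tsv"
        pd.DataFrame([{
            "chrom": l.chrom, "pos": l.pos, "tumor_cov": l.tumor_coverage,
            "normal_cov": l.normal_coverage, "alt_reads": l.alt_reads,
            "total_reads": l.total_reads, "het": int(l.het)}
            for l in loci]).to_csv(path, sep="\t", index=False)
        loaded = read_loci_tsv(path)
        assert len(loaded) == 50
        assert loaded[3].pos == loci[3].pos
        assert loaded[3].het == loci[3].het
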