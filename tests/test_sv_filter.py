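"""Structural-variant filtering, classification and gene-effect annotation."""

import dataclasses

import pytest

from um_landscape.intervals import IntervalMask
from um_landscape.sv_filter import (Breakend, BreakpointPair, SvCall,
                                    SvThresholds, Transcript,
                                    annotate_gene_effects,
                                    breakpoint_reasons, classify_sv,
                                    filter_breakpoints,
                                    flank_similarity_from_sequences,
                                    read_bedpe, recurrent_sv_genes,
                                    write_bedpe)
from um_landscape.synth import SV_VIOLATIONS, simulate_sv_candidates

from .oracles import sv_oracle


def clean_bp(**overrides):
    base = dict(
        end1=Breakend("chr3", 100_000, "+"),
        end2=Breakend("chr3", 250_000, "-"),
        junction_reads=8, mean_junction_mismatches=0.5,
        tumor_coverage_end1=60, tumor_coverage_end2=60,
        normal_coverage_end1=40, normal_coverage_end2=40,
        inserted_bases="", flank_similarity=0.2, sample_id="S1")
    base.update(overrides)
    return BreakpointPair(**base)


SEGDUP = IntervalMask.from_tuples([("chrSD", 1, 10_000)])


class TestFiltering:
    def test_clean_candidate_passes(self):
        passed, rejection = filter_breakpoints([clean_bp()], segdup=SEGDUP)
        assert len(passed) == 1 and len(rejection) == 0

    def test_two_junction_reads_rejected(self):
        passed, rejection = filter_breakpoints([clean_bp(junction_reads=2)],
                                               segdup=SEGDUP)
        assert len(passed) == 0
        assert rejection.iloc[0].reasons == "min_junction_reads"

    def test_flank_similarity_boundary_is_inclusive(self):
        reasons = breakpoint_reasons(clean_bp(flank_similarity=0.90),
                                     SEGDUP, [])
        assert reasons == ["flank_similarity"]
        assert breakpoint_reasons(clean_bp(flank_similarity=0.899),
                                  SEGDUP, []) == []

    def test_planted_violation_fixture_matches_plan_and_oracle(self):
        plan = {cls: 2 for cls in SV_VIOLATIONS}
        plan["clean"] = 10
        candidates, labels = simulate_sv_candidates(plan, seed=21)
        own = [c for c, l in zip(candidates, labels) if l != "planted_twin"]
        passed, rejection = filter_breakpoints(own, segdup=SEGDUP,
                                               cohort=candidates)
        assert len(passed) == 10  # the construction plan
        for bp in own:
            reasons = breakpoint_reasons(bp, SEGDUP, candidates)
            _, oracle_reasons = sv_oracle(
                bp, SEGDUP.contains, candidates)
            assert reasons == oracle_reasons

    def test_oracle_equivalence_on_1000_random_candidates(self):
        plan = {cls: 112 for cls in SV_VIOLATIONS}
        plan["clean"] = 104
        candidates, labels = simulate_sv_candidates(plan, seed=99)
        own = [c for c, l in zip(candidates, labels) if l != "planted_twin"]
        assert len(own) == 1000
        mismatches = 0
        for bp in own:
            got = breakpoint_reasons(bp, SEGDUP, candidates)
            _, want = sv_oracle(bp, SEGDUP.contains, candidates)
            if got != want:
                mismatches += 1
        assert mismatches == 0

    def test_monotonic_under_threshold_tightening(self):
        plan = {cls: 10 for cls in SV_VIOLATIONS}
        candidates, labels = simulate_sv_candidates(plan, seed=31)
        own = [c for c, l in zip(candidates, labels) if l != "planted_twin"]
        base = SvThresholds()
        n_base = len(filter_breakpoints(own, SEGDUP, candidates, base)[0])
        tighter = [
            dataclasses.replace(base, min_junction_reads=5),
            dataclasses.replace(base, max_mean_mismatches=1.0),
            dataclasses.replace(base, max_coverage=500.0),
            dataclasses.replace(base, min_normal_coverage=5.0),
            dataclasses.replace(base, max_flank_similarity=0.5),
            dataclasses.replace(base, max_insertion=1),
            dataclasses.replace(base, multi_sample_window=500),
        ]
        for thresholds in tighter:
            n = len(filter_breakpoints(own, SEGDUP, candidates,
                                       thresholds)[0])
            assert n <= n_base

    def test_rerun_on_survivors_is_idempotent(self):
        plan = {"clean": 10, "multi_sample": 3}
        candidates, labels = simulate_sv_candidates(plan, seed=13)
        own = [c for c, l in zip(candidates, labels) if l != "planted_twin"]
        passed, _ = filter_breakpoints(own, SEGDUP, cohort=candidates)
        again, _ = filter_breakpoints(passed, SEGDUP, cohort=candidates)
        assert [id(b) for b in again] == [id(b) for b in passed]


class TestClassification:
    def test_interchromosomal(self):
        bp = clean_bp(end2=Breakend("chr8", 500, "+"),
                      end1=Breakend("chr6", 500, "+"))
        assert classify_sv(bp) == "interchromosomal"

    def test_deletion_convention(self):
        assert classify_sv(clean_bp()) == "deletion"

    def test_tandem_duplication_convention(self):
        bp = clean_bp(end1=Breakend("chr3", 100_000, "-"),
                      end2=Breakend("chr3", 250_000, "+"))
        assert classify_sv(bp) == "tandem_duplication"

    @pytest.mark.parametrize("o1,o2", [("+", "+"), ("-", "-")])
    def test_inversion_convention(self, o1, o2):
        bp = clean_bp(end1=Breakend("chr3", 100_000, o1),
                      end2=Breakend("chr3", 250_000, o2))
        assert classify_sv(bp) == "inversion"

    def test_orientation_is_position_sorted(self):
        # same junction written with ends swapped classifies identically
        bp = clean_bp(end1=Breakend("chr3", 250_000, "-"),
                      end2=Breakend("chr3", 100_000, "+"))
        assert classify_sv(bp) == "deletion"

    def test_unknown_orientation_rejected(self):
        with pytest.raises(ValueError):
            Breakend("chr1", 100, "fwd")


def two_gene_models():
    """GENE_A on + strand (CDS 1001-1600, one exon), GENE_B on + strand
    (CDS 5001-5600).  Junction points chosen so coding offsets control
    frame compatibility exactly."""
    a = Transcript(gene="GENE_A", chrom="chr1", strand="+",
                   exons=[(1001, 1600)], cds_start=1001, cds_end=1600)
    b = Transcript(gene="GENE_B", chrom="chr2", strand="+",
                   exons=[(5001, 5600)], cds_start=5001, cds_end=5600)
    return [a, b]


def fusion_call(pos_a, pos_b):
    bp = BreakpointPair(
        end1=Breakend("chr1", pos_a, "+"),   # keeps 5' of GENE_A
        end2=Breakend("chr2", pos_b, "-"),   # keeps 3' of GENE_B
        junction_reads=10, mean_junction_mismatches=0.1,
        tumor_coverage_end1=50, tumor_coverage_end2=50,
        normal_coverage_end1=50, normal_coverage_end2=50,
        sample_id="S1")
    return SvCall(breakpoint=bp, sv_class="interchromosomal")


class TestGeneEffects:
    def test_frame_preserving_fusion(self):
        # offsets 300 and 300: both phase 0 -> in frame
        calls = annotate_gene_effects([fusion_call(1301, 5301)],
                                      two_gene_models())
        assert calls[0].gene_effect == "in_frame_fusion"
        assert calls[0].genes == ["GENE_A", "GENE_B"]

    def test_frame_breaking_fusion(self):
        # offsets 300 and 301: phases 0 vs 1 -> out of frame
        calls = annotate_gene_effects([fusion_call(1301, 5302)],
                                      two_gene_models())
        assert calls[0].gene_effect == "out_of_frame_fusion"

    def test_non_coding_partner_is_truncation(self):
        models = two_gene_models()
        models[1] = Transcript(gene="GENE_B", chrom="chr2", strand="+",
                               exons=[(5001, 5600)])
        calls = annotate_gene_effects([fusion_call(1301, 5301)], models)
        assert calls[0].gene_effect == "truncation"

    def test_intronic_deletion(self):
        gene = Transcript(gene="BAP1", chrom="chr3", strand="-",
                          exons=[(1000, 1200), (2000, 2200)],
                          cds_start=1000, cds_end=2200)
        bp = clean_bp(end1=Breakend("chr3", 1400, "+"),
                      end2=Breakend("chr3", 1554, "-"))
        calls = annotate_gene_effects(
            [SvCall(breakpoint=bp, sv_class="deletion")], [gene])
        assert calls[0].gene_effect == "intronic_deletion"

    def test_intergenic(self):
        bp = clean_bp(end1=Breakend("chr9", 10, "+"),
                      end2=Breakend("chr9", 2000, "-"))
        calls = annotate_gene_effects(
            [SvCall(breakpoint=bp, sv_class="deletion")], two_gene_models())
        assert calls[0].gene_effect == "intergenic"

    def test_single_genic_end_truncates(self):
        bp = clean_bp(end1=Breakend("chr1", 1301, "+"),
                      end2=Breakend("chr1", 900_000, "-"))
        calls = annotate_gene_effects(
            [SvCall(breakpoint=bp, sv_class="deletion")], two_gene_models())
        assert calls[0].gene_effect == "truncation"


class TestRecurrence:
    def test_empty(self):
        assert len(recurrent_sv_genes([])) == 0

    def test_same_gene_two_samples(self):
        models = two_gene_models()
        calls = []
        for sample, pos in (("S1", 1301), ("S2", 1310)):
            bp = clean_bp(end1=Breakend("chr1", pos, "+"),
                          end2=Breakend("chr1", 900_000, "-"),
                          sample_id=sample)
            calls.append(SvCall(breakpoint=bp, sv_class="deletion"))
        annotated = annotate_gene_effects(calls, models)
        table = recurrent_sv_genes(annotated)
        assert list(table.gene) == ["GENE_A"]
        assert list(table.n_events) == [2]

    def test_planted_three_hit_gene(self):
        models = two_gene_models()
        calls = []
        for sample in ("S1", "S2", "S3"):
            bp = clean_bp(end1=Breakend("chr2", 5100, "+"),
                          end2=Breakend("chr2", 900_000, "-"),
                          sample_id=sample)
            calls.append(SvCall(breakpoint=bp, sv_class="deletion"))
        annotated = annotate_gene_effects(calls, models)
        table = recurrent_sv_genes(annotated)
        assert table[table.gene == "GENE_B"].n_events.iloc[0] == 3


class TestHelpers:
    def test_flank_similarity_identical(self):
        assert flank_similarity_from_sequences("ACGT" * 5, "ACGT" * 5) == 1.0

    def test_flank_similarity_counts_edits(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "ACGTACGTACGAACGTACGT"  # one substitution
        assert flank_similarity_from_sequences(a, b) == pytest.approx(19 / 20)

    def test_bedpe_round_trip(self, tmp_path):
        plan = {"clean": 5, "long_insertion": 2}
        candidates, _ = simulate_sv_candidates(plan, seed=2)
        path = tmp_path / "cands.bedpe"
        write_bedpe(candidates, path)
        loaded = read_bedpe(path)
        assert len(loaded) == len(candidates)
        for a, b in zip(candidates, loaded):
            assert a.end1 == b.end1 and a.end2 == b.end2
            assert a.inserted_bases == b.inserted_bases
            assert a.flank_similarity == pytest.approx(b.flank_similarity)
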