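"""Novel miRNA discovery: mapping, excision, MFEI, hairpin screen, gating."""

import random

import pytest

from mirprof.cleaning import UniqueTag
from mirprof.fold import fold
from mirprof.novel import (
    GenomeHit,
    call_novel,
    compute_mfei,
    discover_novel,
    evaluate_candidate,
    excise_precursors,
    hairpin_criteria,
    map_to_genome,
)
from mirprof.seqio import canonical, reverse_complement
from mirprof.simulate import HairpinDesign, build_genome, make_hairpin_precursor


def naive_scan(tag, genome, max_mismatch=0):
    """Brute-force sliding-window mapping oracle."""
    hits = []
    for contig, seq in genome.items():
        seq = canonical(seq)
        for strand, query in (("+", canonical(tag)), ("-", reverse_complement(tag))):
            L = len(query)
            for start in range(len(seq) - L + 1):
                mm = sum(a != b for a, b in zip(query, seq[start : start + L]))
                if mm <= max_mismatch:
                    hits.append((contig, start, strand, mm))
    return sorted(hits)


class TestMapping:
    def test_planted_tag_found_at_exact_coordinate(self):
        design = HairpinDesign(
            mature="ACGTGGCATCGATCGGATCCAT", arm="5p", loop_length=8,
            genome_position=("chr1", 500, "+"),
        )
        genome = build_genome([design], 2000, seed=1)
        hits = map_to_genome([UniqueTag(design.mature, 9)], genome)
        assert any(h.start == 500 and h.strand == "+" for h in hits)

    def test_absent_tag_has_no_hits(self):
        genome = {"chr1": "A" * 500}
        assert map_to_genome([UniqueTag("C" * 20, 1)], genome) == []

    def test_minus_strand_hit(self):
        insert = "ACGTGGCATCGATCGGATCCAT"
        genome = {"chr1": "T" * 100 + reverse_complement(insert) + "T" * 100}
        hits = map_to_genome([UniqueTag(insert, 1)], genome)
        assert len(hits) == 1 and hits[0].strand == "-" and hits[0].start == 100

    def test_equals_naive_sliding_window_scan(self):
        rng = random.Random(21)
        genome = {"chr1": "".join(rng.choice("ACGT") for _ in range(5000))}
        tags = [
            UniqueTag("".join(rng.choice("ACGT") for _ in range(16)), 1) for _ in range(40)
        ]
        # plant a few, one with a mismatch
        tags[0] = UniqueTag(genome["chr1"][100:120], 1)
        mutated = list(genome["chr1"][300:320])
        mutated[10] = "A" if mutated[10] != "A" else "C"
        tags[1] = UniqueTag("".join(mutated), 1)
        for budget in (0, 1):
            got = {
                (h.tag_sequence, h.contig, h.start, h.strand, h.mismatches)
                for h in map_to_genome(tags, genome, max_mismatch=budget)
            }
            expected = {
                (canonical(t.sequence), c, s, strand, mm)
                for t in tags
                for c, s, strand, mm in naive_scan(t.sequence, genome, budget)
            }
            assert got == expected


class TestExcision:
    def test_window_arithmetic(self):
        genome = {"chr1": "A" * 10000}
        hit = GenomeHit("G" * 22, "chr1", 5000, 5022, "+", 0)
        windows = excise_precursors(hit, genome, flank=150)
        assert all(len(seq) <= 192 for seq, _, _ in windows)
        assert len(windows) == 2

    def test_left_clipped_window_near_contig_start(self):
        genome = {"chr1": "A" * 1000}
        hit = GenomeHit("G" * 22, "chr1", 10, 32, "+", 0)
        windows = excise_precursors(hit, genome, flank=150)
        starts = [w[1][1] for w in windows]
        assert min(starts) == 0  # left-clipped instead of out of bounds
        for seq, (_, wstart, wend, _), offset in windows:
            assert len(seq) == wend - wstart

    def test_minus_strand_window_contains_mature_in_tag_orientation(self):
        mature = "ACGTGGCATCGATCGGATCCAT"
        genome = {"chr1": "T" * 200 + reverse_complement(mature) + "T" * 200}
        hit = GenomeHit(mature, "chr1", 200, 222, "-", 0)
        for seq, window, offset in excise_precursors(hit, genome, flank=50):
            assert seq[offset : offset + 22] == mature

    def test_planted_hairpin_window_contains_designed_precursor(self):
        design = HairpinDesign(
            mature="ACGTGGCATCGATCGGATCCAT", arm="5p", loop_length=10,
            genome_position=("chr1", 1000, "+"),
        )
        genome = build_genome([design], 5000, seed=3)
        pre = make_hairpin_precursor(design, rng_seed=3 + 0)
        hit = GenomeHit(canonical(design.mature), "chr1", 1000, 1022, "+", 0)
        windows = excise_precursors(hit, genome, flank=150)
        # the [start-20, end+flank) window spans mature+loop+star for a 5p design
        assert any(genome["chr1"][1000 : 1000 + design.precursor_length] in seq for seq, _, _ in windows)


class TestMfei:
    def test_arithmetic_identity(self):
        amfe, mfei = compute_mfei(-50.0, 100, 50.0)
        assert (amfe, mfei) == (50.0, 1.0)

    def test_threshold_boundary_value(self):
        _, mfei = compute_mfei(-35.0, 100, 50.0)
        assert mfei == pytest.approx(0.70)

    def test_zero_energy_gives_zero_index(self):
        assert compute_mfei(0.0, 100, 50.0) == (0.0, 0.0)

    def test_degenerate_gc_rejected(self):
        with pytest.raises(ValueError):
            compute_mfei(-10.0, 100, 0.0)

    def test_invariant_under_u_t_rewriting(self):
        seq = "GGGGAAAACCCCTTTTGGGGAAAACCCC" * 3
        for variant in (seq, seq.replace("T", "U")):
            cand = evaluate_candidate(variant, ("c", 0, len(seq), "+"), 0, 22, 10)
            assert cand.mfei == pytest.approx(
                (abs(cand.mfe) / len(seq) * 100) / cand.gc_percent
            )


class TestHairpinCriteria:
    def _design_candidate(self, stem_mismatches=0, arm="5p", seed=5):
        design = HairpinDesign(
            mature="ACGTGGCATCGATCGGATCCAT", arm=arm, loop_length=8,
            stem_mismatches=stem_mismatches,
        )
        pre = make_hairpin_precursor(design, rng_seed=seed)
        offset = 0 if arm == "5p" else len(pre) - 22
        return pre, offset

    @pytest.mark.parametrize("arm", ["5p", "3p"])
    def test_designed_hairpin_passes_with_correct_arm(self, arm):
        pre, offset = self._design_candidate(arm=arm)
        structure, _ = fold(pre)
        passed, reasons, got_arm = hairpin_criteria(structure, offset, 22)
        assert passed, reasons
        assert got_arm == arm

    def test_two_mismatch_stem_still_passes(self):
        pre, offset = self._design_candidate(stem_mismatches=2)
        structure, _ = fold(pre)
        passed, reasons, _ = hairpin_criteria(structure, offset, 22)
        assert passed, reasons

    def test_mature_across_loop_fails_with_loop_overlap(self):
        pre, _ = self._design_candidate()
        structure, _ = fold(pre)
        # place the mature window across the terminal loop (positions 12-34)
        passed, reasons, _ = hairpin_criteria(structure, 12, 22)
        assert not passed
        assert "loop overlap" in reasons

    def test_unstructured_window_fails(self):
        structure = "." * 60
        passed, reasons, arm = hairpin_criteria(structure, 10, 22)
        assert not passed and arm is None
        assert "insufficient mature pairing" in reasons

    def test_random_windows_rarely_pass(self):
        rng = random.Random(17)
        n_pass = 0
        n_windows = 60
        for _ in range(n_windows):
            seq = "".join(rng.choice("ACGT") for _ in range(120))
            structure, _ = fold(seq)
            passed, _, _ = hairpin_criteria(structure, 49, 22)
            n_pass += passed
        assert n_pass / n_windows < 0.10  # empirical null well below half


class TestCallNovel:
    def _candidate(self, mfei, count, mature="ACGTGGCATCGATCGGATCCAT", arm="5p"):
        from mirprof.novel import PrecursorCandidate

        return PrecursorCandidate(
            sequence=mature + "N" * 78, window=("chr1", 0, 100, "+"),
            structure="." * 100,
            mfe=-30.0, amfe=30.0, gc_percent=40.0, mfei=mfei, mature_offset=0,
            mature_length=len(mature), read_count=count, mature_arm=arm, passed=True,
        )

    def test_boundary_mfei_retained_and_below_rejected(self):
        calls = call_novel([self._candidate(0.70, 10)])
        assert len(calls) == 1
        calls = call_novel([self._candidate(0.69, 10)])
        assert len(calls) == 0

    def test_copy_threshold_boundary(self):
        assert len(call_novel([self._candidate(0.9, 5)])) == 1
        assert len(call_novel([self._candidate(0.9, 4)])) == 0

    def test_multi_locus_mature_collapsed_to_max_mfei(self):
        a = self._candidate(0.80, 10)
        b = self._candidate(0.95, 10)
        calls = call_novel([a, b])
        assert len(calls) == 1
        assert calls.iloc[0]["mfei"] == pytest.approx(0.95)

    def test_names_ordered_by_read_count(self):
        a = self._candidate(0.9, 50, mature="A" * 22)
        b = self._candidate(0.9, 90, mature="C" * 22)
        calls = call_novel([a, b])
        assert list(calls["name"]) == ["mko-miRN1-5p", "mko-miRN2-5p"]
        assert calls.iloc[0]["read_count"] == 90

    def test_threshold_monotonicity(self, study, study_result):
        cands = [c for c in study_result["candidates"]]
        base = set(call_novel(cands)["sequence"])
        looser = set(call_novel(cands, mfei_threshold=0.5, copy_threshold=1)["sequence"])
        assert base <= looser


class TestDiscovery:
    def test_planted_hairpins_recovered_exactly(self, study, study_result):
        from mirprof.pipeline import score_novel_recovery

        scores = score_novel_recovery(study, study_result["novel_calls"])
        assert scores["sensitivity"] == 1.0
        assert scores["false_calls"] == 0.0

    def test_subthreshold_copies_yield_no_calls(self):
        from mirprof.pipeline import make_study_bundle, run_pipeline

        bundle = make_study_bundle(
            seed=11, n_reads=800, genome_length=12000, n_hairpins=2,
            hairpin_copies=(2, 4), n_conserved=3, contaminant_fraction=0.0,
        )
        result = run_pipeline(bundle)
        assert len(result["novel_calls"]) == 0

    def test_call_counts_match_truth_counts(self, study, study_result):
        truth_counts = {
            canonical(d.mature): c for d, c in study["planted_hairpins"]
        }
        for row in study_result["novel_calls"].itertuples():
            assert truth_counts[row.sequence] == row.read_count
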