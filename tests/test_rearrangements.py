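"""Inversion/translocation calling, detection limits, span support, genotypes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vmk import (
    EditSpec,
    apply_edits,
    assign_scaffolds,
    best_hits,
    call_inversions,
    call_translocations,
    generate_markers,
    genotype_matrix,
    guaranteed_detectable_length,
    orient_placements,
    place_markers,
    random_genome,
    segment_blocks,
    span_support,
)
from vmk.comparative import CollinearBlock, ScaffoldAssignment
from vmk.markers import MarkerSetSpec
from vmk.rearrangements import RearrangementCall

from test_comparative import S, pm


def _call_pipeline(reference, assembly, spec, min_markers=2):
    markers = generate_markers(reference, spec)
    placed = best_hits(place_markers(markers, assembly), score="identity")
    lengths = {r.id: len(r) for r in assembly}
    assigns = assign_scaffolds(placed, lengths)
    oriented = orient_placements(placed, assigns, lengths)
    blocks = segment_blocks(oriented, spec.spacing)
    inv = call_inversions(blocks, spec.spacing, min_markers)
    trans = call_translocations(oriented, assigns, spec.spacing, min_markers)
    return inv, trans


class TestGuaranteedDetectableLength:
    def _oracle(self, s, m, k):
        """Direct enumeration: smallest L covering k full markers at every offset."""
        L = m
        while True:
            ok = True
            for a in range(s):
                count = sum(
                    1
                    for i in range((a + L) // s + 2)
                    if i * s >= a and i * s + m <= a + L
                )
                if count < k:
                    ok = False
                    break
            if ok:
                return L
            L += 1

    @pytest.mark.parametrize("s,m,k", [(40, 7, 1), (40, 7, 2), (53, 11, 3), (30, 5, 2)])
    def test_matches_enumeration_oracle(self, s, m, k):
        assert guaranteed_detectable_length(s, m, k) == self._oracle(s, m, k)

    def test_megabase_grid_limit_is_two_megabases(self):
        """At 1-Mb spacing, only inversions of ~2 Mb always span two markers."""
        assert guaranteed_detectable_length(1_000_000, 2_000, 2) == 2_001_999

    def test_hundred_kb_grid_limit_is_in_the_200_300_kb_band(self):
        limit = guaranteed_detectable_length(100_000, 2_000, 2)
        assert limit == 201_999
        assert 200_000 <= limit <= 300_000

    @pytest.mark.parametrize("s", [10_000, 100_000, 1_000_000])
    def test_single_marker_closed_form(self, s):
        m = 2_000
        assert guaranteed_detectable_length(s, m, 1) == s + m - 1

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            guaranteed_detectable_length(1_000, 2_000, 2)
        with pytest.raises(ValueError):
            guaranteed_detectable_length(1_000_000, 2_000, 0)


class TestCallInversions:
    def test_minus_blocks_above_threshold_become_calls(self):
        blocks = [
            CollinearBlock("c", "sc", 1, 0, 3 * S, 0, 3 * S + 500, 4),
            CollinearBlock("c", "sc", -1, 4 * S, 6 * S, 4 * S, 6 * S + 500, 3),
            CollinearBlock("c", "sc", -1, 8 * S, 8 * S, 8 * S, 8 * S + 500, 1),
        ]
        calls = call_inversions(blocks, S, min_markers=2)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end) == (4 * S + 1, 7 * S + 1)
        assert c.start % S == 1 and c.end % S == 1
        assert c.n_markers == 3

    def test_identity_assembly_has_zero_calls(self, toy_ref, toy_spec):
        inv, trans = _call_pipeline(toy_ref, toy_ref, toy_spec)
        assert inv == [] and trans == []

    def test_planted_inversion_recovered_within_one_grid_step(self):
        """A 3-Mb inversion at 4,000,001-7,000,000 is called to <=100 kb per side."""
        spec = MarkerSetSpec(spacing=100_000, marker_len=2_000)
        ref = random_genome([10_000_000], seed=5)
        edit = EditSpec("inversion", "chr1", 4_000_001, 7_000_000)
        edited, _ = apply_edits(ref, [edit])
        inv, trans = _call_pipeline(ref, edited, spec)
        assert trans == []
        assert len(inv) == 1
        call = inv[0]
        assert abs(call.start - edit.start) <= spec.spacing
        assert abs(call.end - edit.end) <= spec.spacing

    def test_short_inversion_straddling_one_marker_is_missed(self):
        """A 1.5-Mb inversion covering a single 1-Mb-grid marker yields no call,
        consistent with the grid's ~2-Mb guaranteed detection limit."""
        spec = MarkerSetSpec(spacing=1_000_000, marker_len=2_000)
        ref = random_genome([4_000_000], seed=6)
        # offset chosen so only the marker at 1,000,001 lies fully inside
        edit = EditSpec("inversion", "chr1", 2_501, 1_502_500)
        edited, _ = apply_edits(ref, [edit])
        inv, trans = _call_pipeline(ref, edited, spec)
        assert inv == [] and trans == []

    def test_involution_two_applications_cancel(self):
        spec = MarkerSetSpec(spacing=100_000, marker_len=2_000)
        ref = random_genome([5_000_000], seed=7)
        edit = EditSpec("inversion", "chr1", 1_000_001, 4_000_000)
        once, _ = apply_edits(ref, [edit])
        twice, _ = apply_edits(once, [edit])
        inv, trans = _call_pipeline(ref, twice, spec)
        assert inv == [] and trans == []
        assert twice[0].seq == ref[0].seq


class TestCallTranslocations:
    def _assigns(self):
        return [
            ScaffoldAssignment("sc1", "chr1", 50, "+", True, 900_000),
            ScaffoldAssignment("sc3", "chr3", 50, "+", True, 800_000),
        ]

    def test_marker_run_on_foreign_scaffold_is_called(self):
        placements = [pm("chr1", i, "sc1", i * S) for i in range(5)] + [
            pm("chr1", 5 + j, "sc3", j * S) for j in range(5)
        ]
        calls = call_translocations(placements, self._assigns(), S, min_markers=2)
        assert len(calls) == 1
        c = calls[0]
        assert c.type == "translocation" and c.n_markers == 5
        assert (c.start, c.end) == (5 * S + 1, 10 * S + 1)

    def test_single_stray_marker_below_threshold_ignored(self):
        placements = [pm("chr1", i, "sc1", i * S) for i in range(5)] + [
            pm("chr1", 5, "sc3", 0)
        ]
        assert call_translocations(placements, self._assigns(), S, min_markers=2) == []

    def test_planted_translocation_recovered(self):
        """Markers of a moved 1-Mb block land on the destination chromosome."""
        spec = MarkerSetSpec(spacing=100_000, marker_len=2_000)
        ref = random_genome([6_000_000, 4_000_000], seed=8)
        edit = EditSpec(
            "translocation", "chr1", 2_000_001, 3_000_000, dest_chrom="chr2", dest_pos=1_500_001
        )
        edited, _ = apply_edits(ref, [edit])
        inv, trans = _call_pipeline(ref, edited, spec)
        assert inv == []
        assert len(trans) == 1
        c = trans[0]
        assert c.chrom == "chr1"
        assert abs(c.start - edit.start) <= spec.spacing
        assert abs(c.end - edit.end) <= spec.spacing


class TestSpanSupport:
    def test_spanning_alignment_counted(self):
        assert span_support([(0, 50_000)], 25_000) == 1

    def test_boundary_is_inclusive(self):
        assert span_support([(0, 35_000)], 25_000, flank=10_000) == 1
        assert span_support([(0, 34_999)], 25_000, flank=10_000) == 0
        assert span_support([(15_000, 50_000)], 25_000, flank=10_000) == 1
        assert span_support([(15_001, 50_000)], 25_000, flank=10_000) == 0

    def test_named_intervals_accepted(self):
        assert span_support([("read1", 0, 50_000)], 25_000) == 1

    def test_nonpositive_flank_rejected(self):
        with pytest.raises(ValueError):
            span_support([(0, 1)], 0, flank=0)

    def test_matches_brute_force_predicate(self, rng):
        intervals = [
            (int(a), int(a + rng.integers(1, 60_000)))
            for a in rng.integers(0, 100_000, size=200)
        ]
        bp, flank = 50_000, 10_000
        oracle = sum(1 for s, e in intervals if s <= bp - flank and e >= bp + flank)
        assert span_support(intervals, bp, flank) == oracle


class TestGenotypeMatrix:
    def _call(self, start, end, label="", chrom="chr1", type_="inversion"):
        return RearrangementCall(type_, chrom, start, end, 5, "sc", label)

    def test_single_assembly_single_call(self):
        gm = genotype_matrix({"a1": [self._call(1, 100_001)]})
        assert gm.frame.shape == (1, 1)
        assert bool(gm.frame.iloc[0, 0])

    def test_identical_calls_merge_into_one_locus(self):
        gm = genotype_matrix(
            {
                "a1": [self._call(1_000_001, 4_000_001)],
                "a2": [self._call(1_000_001, 4_000_001)],
                "a3": [],
            }
        )
        assert gm.frame.shape == (1, 3)
        assert gm.frame.iloc[0].tolist() == [True, True, False]

    def test_half_overlap_stays_separate_at_point8(self):
        gm = genotype_matrix(
            {"a1": [self._call(1, 2_000_000)], "a2": [self._call(1_000_001, 3_000_000)]},
            reciprocal_overlap=0.8,
        )
        assert gm.frame.shape == (2, 2)

    def test_different_types_never_merge(self):
        gm = genotype_matrix(
            {
                "a1": [self._call(1, 2_000_000)],
                "a2": [self._call(1, 2_000_000, type_="translocation")],
            }
        )
        assert gm.frame.shape == (2, 2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            genotype_matrix({})
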