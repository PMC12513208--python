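"""Scaffold assignment, block segmentation, and linearity metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vmk import (
    SequenceRecord,
    assign_scaffolds,
    best_hits,
    generate_markers,
    linearity_metrics,
    orient_placements,
    place_markers,
    reverse_complement,
    segment_blocks,
)
from vmk.comparative import lis_length
from vmk.mapping import PlacedMarker

S = 10_000  # grid spacing used by the hand-built chains below
M = 500


def pm(chrom, i, subject, subj_start, strand="+", ambiguous=False):
    """A placed marker at grid index i."""
    return PlacedMarker(
        marker_id=f"{chrom}_{i * S + 1}",
        ref_chrom=chrom,
        ref_start=i * S,
        subject_id=subject,
        subject_start=subj_start,
        subject_end=subj_start + M,
        strand=strand,
        pident=100.0,
        ambiguous=ambiguous,
    )


class TestAssignScaffolds:
    def test_majority_vote(self):
        placements = [pm("chrA", i, "sc1", i * S) for i in range(60)] + [
            pm("chrB", i, "sc1", i * S) for i in range(40)
        ]
        (a,) = assign_scaffolds(placements, {"sc1": 1_000_000})
        assert a.chrom == "chrA" and a.n_support == 60 and a.orientation == "+"
        assert a.is_primary

    def test_reverse_complement_scaffold_gets_minus_orientation(self, toy_ref, toy_spec):
        chrom = toy_ref[0]
        markers = generate_markers([chrom], toy_spec)
        rc = [SequenceRecord("rc", reverse_complement(chrom.seq))]
        placed = best_hits(place_markers(markers, rc), score="identity")
        (a,) = assign_scaffolds(placed, {"rc": len(chrom.seq)})
        assert a.chrom == chrom.id and a.orientation == "-"

    def test_tie_breaks_to_lexicographically_smaller_chrom(self, caplog):
        placements = [pm("chrB", i, "sc1", i * S) for i in range(5)] + [
            pm("chrA", i, "sc1", (i + 10) * S) for i in range(5)
        ]
        with caplog.at_level("INFO"):
            (a,) = assign_scaffolds(placements, {"sc1": 500_000})
        assert a.chrom == "chrA"
        assert "tie" in caplog.text

    def test_primary_is_longest_assigned_scaffold(self):
        placements = [pm("chrA", i, "small", i * S) for i in range(10)] + [
            pm("chrA", i + 10, "big", i * S) for i in range(5)
        ]
        assigns = assign_scaffolds(placements, {"small": 100_000, "big": 900_000})
        primary = {a.subject_id: a.is_primary for a in assigns}
        assert primary == {"small": False, "big": True}

    def test_no_placements_raises(self):
        with pytest.raises(ValueError):
            assign_scaffolds([], {})


class TestSegmentBlocks:
    def test_collinear_run_is_one_block(self):
        placements = [pm("c", i, "sc", i * S) for i in range(10)]
        (b,) = segment_blocks(placements, S)
        assert (b.sign, b.n_markers) == (1, 10)
        assert (b.ref_first, b.ref_last) == (0, 9 * S)

    def test_inverted_middle_yields_three_signed_blocks(self):
        """Forward 1-3, inverted 4-6 (reversed subject order, minus), forward 7-10."""
        fwd1 = [pm("c", i, "sc", i * S) for i in range(3)]
        inv = [pm("c", 3 + j, "sc", (5 - j) * S, strand="-") for j in range(3)]
        fwd2 = [pm("c", i, "sc", i * S) for i in range(6, 10)]
        blocks = segment_blocks(fwd1 + inv + fwd2, S)
        assert [b.sign for b in blocks] == [1, -1, 1]
        assert [b.n_markers for b in blocks] == [3, 3, 4]

    def test_subject_jump_mid_chain_breaks_twice(self):
        placements = [pm("c", i, "sc", i * S) for i in range(10)]
        placements[5] = pm("c", 5, "other", 5 * S)
        blocks = segment_blocks(placements, S)
        assert [b.subject_id for b in blocks] == ["sc", "other", "sc"]
        assert [b.n_markers for b in blocks] == [5, 1, 4]

    def test_gap_tolerance_bounds_subject_jumps(self):
        """A 2-grid-step subject insertion is bridged at gap_tol=3, split at 1."""
        placements = [
            pm("c", i, "sc", i * S + (2 * S if i >= 6 else 0)) for i in range(12)
        ]
        (b,) = segment_blocks(placements, S, gap_tol=3)
        assert b.n_markers == 12
        blocks = segment_blocks(placements, S, gap_tol=1)
        assert [b.n_markers for b in blocks] == [6, 6]

    def test_missing_markers_do_not_fragment_a_clean_chain(self):
        placements = [pm("c", i, "sc", i * S) for i in range(12) if i not in (4, 5)]
        (b,) = segment_blocks(placements, S, gap_tol=3)
        assert b.n_markers == 10

    def test_identity_yields_one_plus_block_per_chromosome(self, toy_ref, toy_markers):
        placed = best_hits(place_markers(toy_markers, toy_ref), score="identity")
        lengths = {r.id: len(r) for r in toy_ref}
        assigns = assign_scaffolds(placed, lengths)
        blocks = segment_blocks(orient_placements(placed, assigns, lengths), 10_000)
        assert len(blocks) == len(toy_ref)
        assert all(b.sign == 1 for b in blocks)

    def test_invariant_under_whole_scaffold_reverse_complement(self, toy_ref, toy_spec):
        """Orientation normalization makes blocks identical for seq and revcomp."""
        chrom = toy_ref[0]
        markers = generate_markers([chrom], toy_spec)
        L = len(chrom.seq)

        def blocks_of(assembly):
            placed = best_hits(place_markers(markers, assembly), score="identity")
            lengths = {r.id: len(r) for r in assembly}
            assigns = assign_scaffolds(placed, lengths)
            oriented = orient_placements(placed, assigns, lengths)
            return [
                (b.chrom, b.sign, b.ref_first, b.ref_last, b.subject_min, b.n_markers)
                for b in segment_blocks(oriented, toy_spec.spacing)
            ]

        fwd = blocks_of([SequenceRecord("s", chrom.seq)])
        rev = blocks_of([SequenceRecord("s", reverse_complement(chrom.seq))])
        assert fwd == rev

    def test_marker_count_conserved_and_ambiguous_excluded(self, rng):
        placements = []
        for i in range(50):
            strand = "-" if rng.integers(0, 4) == 0 else "+"
            subj = int(rng.integers(0, 60)) * S
            placements.append(
                pm("c", i, f"sc{int(rng.integers(0, 3))}", subj, strand, bool(rng.integers(0, 5) == 0))
            )
        blocks = segment_blocks(placements, S)
        n_unamb = sum(1 for p in placements if not p.ambiguous)
        assert sum(b.n_markers for b in blocks) == n_unamb


class TestLis:
    @given(st.lists(st.integers(min_value=0, max_value=60), max_size=40))
    def test_matches_quadratic_oracle(self, values):
        n = len(values)
        best = [1] * n
        for i in range(n):
            for j in range(i):
                if values[j] < values[i]:
                    best[i] = max(best[i], best[j] + 1)
        assert lis_length(values) == (max(best) if n else 0)


class TestLinearityMetrics:
    def _pipeline(self, markers, assembly, expected):
        placed = best_hits(place_markers(markers, assembly), score="identity")
        lengths = {r.id: len(r) for r in assembly}
        assigns = assign_scaffolds(placed, lengths)
        oriented = orient_placements(placed, assigns, lengths)
        return linearity_metrics(oriented, assigns, expected)

    def test_identity_assembly_is_fully_recovered(self, toy_ref, toy_markers):
        df = self._pipeline(toy_markers, toy_ref, toy_markers.count_by_chrom())
        assert (df["recovery"] == 1.0).all()
        assert (df["primary_recovery"] == 1.0).all()
        assert (df["collinearity"] == 1.0).all()

    def test_missing_loci_reduce_recovery_proportionally(self):
        expected = {"c": 100}
        placements = [pm("c", i, "sc", i * S) for i in range(95)]
        assigns = assign_scaffolds(placements, {"sc": 2_000_000})
        df = linearity_metrics(placements, assigns, expected)
        assert df.loc["c", "recovery"] == pytest.approx(0.95)

    def test_collinearity_equals_lis_fraction_on_permuted_chain(self, rng):
        """An inverted segment drops collinearity by exactly the LIS deficit."""
        order = list(range(100))
        order[40:60] = order[40:60][::-1]  # 2-Mb inversion at 100-kb-style grid
        placements = [pm("c", i, "sc", order[i] * S) for i in range(100)]
        assigns = assign_scaffolds(placements, {"sc": 2_000_000})
        df = linearity_metrics(placements, assigns, {"c": 100})
        assert df.loc["c", "collinearity"] == pytest.approx(lis_length([o * S for o in order]) / 100)
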