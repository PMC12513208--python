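"""Scaffold-to-chromosome assignment, collinear blocks, linearity metrics.

The placed markers of one assembly are summarized in three steps:

1. each scaffold is assigned to the chromosome contributing the majority
   of its placed markers, with a majority-strand orientation and a
   per-chromosome "primary" (longest assigned) scaffold;
2. placements are re-expressed in each scaffold's dominant orientation
   (Hi-C scaffolds have arbitrary strand, so inversions must be read
   relative to the scaffold's own frame, not the file's);
3. the oriented placements are segmented into signed collinear blocks —
   maximal runs of markers on one scaffold, one strand, with bounded
   positional jumps.  Sign -1 blocks are anti-diagonal runs, i.e.
   inversion candidates.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .mapping import PlacedMarker

logger = logging.getLogger(__name__)

__all__ = [
    "ScaffoldAssignment",
    "CollinearBlock",
    "assign_scaffolds",
    "orient_placements",
    "segment_blocks",
    "linearity_metrics",
    "lis_length",
]


@dataclass(frozen=True)
class ScaffoldAssignment:
    subject_id: str
    chrom: str
    n_support: int
    orientation: str  # dominant strand of the supporting markers
    is_primary: bool  # longest scaffold assigned to this chromosome
    length: int


@dataclass(frozen=True)
class CollinearBlock:
    """A maximal signed run of consecutively placed markers.

    ``ref_first``/``ref_last`` are the 0-based reference starts of the
    first and last member markers; subject coordinates span the member
    placements (0-based half-open, orientation-normalized).
    """

    chrom: str
    subject_id: str
    sign: int
    ref_first: int
    ref_last: int
    subject_min: int
    subject_max: int
    n_markers: int


def assign_scaffolds(
    placements: Sequence[PlacedMarker], assembly_lengths: Mapping[str, int]
) -> list[ScaffoldAssignment]:
    """Majority-vote each scaffold to a chromosome.

    Ties go to the lexicographically smaller chromosome name (logged).
    Orientation is the majority strand among the supporting markers; the
    primary scaffold of a chromosome is the longest one assigned to it.
    """
    if not placements:
        raise ValueError("no placements to assign")
    votes: dict[str, Counter] = {}
    strands: dict[tuple[str, str], Counter] = {}
    for p in placements:
        votes.setdefault(p.subject_id, Counter())[p.ref_chrom] += 1
        strands.setdefault((p.subject_id, p.ref_chrom), Counter())[p.strand] += 1

    assignments = []
    for subject in sorted(votes):
        counter = votes[subject]
        ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        chrom, n_support = ranked[0]
        if len(ranked) > 1 and ranked[1][1] == n_support:
            logger.info(
                "scaffold %s: tie between chromosomes %s and %s (%d markers each); "
                "assigned to %s",
                subject,
                chrom,
                ranked[1][0],
                n_support,
                chrom,
            )
        sc = strands[(subject, chrom)]
        orientation = "+" if sc["+"] >= sc["-"] else "-"
        assignments.append(
            ScaffoldAssignment(
                subject_id=subject,
                chrom=chrom,
                n_support=n_support,
                orientation=orientation,
                is_primary=False,
                length=int(assembly_lengths.get(subject, 0)),
            )
        )

    # one primary per chromosome: longest assigned scaffold, ties by name
    by_chrom: dict[str, list[ScaffoldAssignment]] = {}
    for a in assignments:
        by_chrom.setdefault(a.chrom, []).append(a)
    primaries = {
        chrom: sorted(group, key=lambda a: (-a.length, a.subject_id))[0].subject_id
        for chrom, group in by_chrom.items()
    }
    return [
        replace(a, is_primary=(primaries[a.chrom] == a.subject_id)) for a in assignments
    ]


def orient_placements(
    placements: Sequence[PlacedMarker],
    assignments: Sequence[ScaffoldAssignment],
    assembly_lengths: Mapping[str, int],
) -> list[PlacedMarker]:
    """Mirror placements on minus-oriented scaffolds into the + frame.

    After this, a scaffold that is simply the reverse complement of its
    chromosome produces strand-+ placements on the y = x diagonal, and a
    genuine inversion inside it still shows as a strand-minus run.
    """
    ori = {a.subject_id: a.orientation for a in assignments}
    out = []
    for p in placements:
        if ori.get(p.subject_id, "+") == "-":
            L = assembly_lengths[p.subject_id]
            out.append(
                replace(
                    p,
                    subject_start=L - p.subject_end,
                    subject_end=L - p.subject_start,
                    strand="-" if p.strand == "+" else "+",
                )
            )
        else:
            out.append(p)
    return out


def segment_blocks(
    placements: Sequence[PlacedMarker], spacing: int, gap_tol: int = 3
) -> list[CollinearBlock]:
    """Chain oriented placements into signed collinear blocks.

    Walking the (unambiguous) markers of each chromosome in reference
    order, the current block is extended while the next marker sits on
    the same subject, the same normalized strand, and its subject jump is
    consistent with the reference jump:
    ``|d_subject - sign * d_ref| <= gap_tol * spacing``.
    Otherwise a new block opens.  ``gap_tol`` grid steps of slack keep
    isolated masked or unmapped markers from fragmenting blocks.
    """
    usable = sorted(
        (p for p in placements if not p.ambiguous),
        key=lambda p: (p.ref_chrom, p.ref_start),
    )
    blocks: list[CollinearBlock] = []
    cur: dict | None = None
    tol = gap_tol * spacing

    def flush() -> None:
        if cur is not None:
            blocks.append(
                CollinearBlock(**{k: v for k, v in cur.items() if not k.startswith("_")})
            )

    for p in usable:
        sign = p.sign
        if cur is not None:
            same_chain = (
                cur["chrom"] == p.ref_chrom
                and cur["subject_id"] == p.subject_id
                and cur["sign"] == sign
                and abs(
                    (p.subject_start - cur["_last_subject"])
                    - sign * (p.ref_start - cur["ref_last"])
                )
                <= tol
            )
        else:
            same_chain = False
        if same_chain:
            cur["ref_last"] = p.ref_start
            cur["subject_min"] = min(cur["subject_min"], p.subject_start)
            cur["subject_max"] = max(cur["subject_max"], p.subject_end)
            cur["n_markers"] += 1
            cur["_last_subject"] = p.subject_start
        else:
            flush()
            cur = dict(
                chrom=p.ref_chrom,
                subject_id=p.subject_id,
                sign=sign,
                ref_first=p.ref_start,
                ref_last=p.ref_start,
                subject_min=p.subject_start,
                subject_max=p.subject_end,
                n_markers=1,
                _last_subject=p.subject_start,
            )
    flush()
    return blocks


def lis_length(values: Sequence[int]) -> int:
    """Length of the longest strictly increasing subsequence (O(n log n))."""
    tails: list[int] = []
    for v in values:
        i = bisect_left(tails, v)
        if i == len(tails):
            tails.append(v)
        else:
            tails[i] = v
    return len(tails)


def linearity_metrics(
    placements: Sequence[PlacedMarker],
    assignments: Sequence[ScaffoldAssignment],
    expected_markers: Mapping[str, int],
) -> pd.DataFrame:
    """Per-chromosome recovery and collinearity summary.

    * ``recovery``: placed markers / expected markers,
    * ``primary_recovery``: markers placed on the chromosome's primary
      scaffold / expected,
    * ``collinearity``: longest strictly increasing run of
      orientation-normalized subject positions (unambiguous markers, in
      reference order) divided by the number of those markers.

    ``placements`` should already be orientation-normalized.
    """
    primary = {a.chrom: a.subject_id for a in assignments if a.is_primary}
    rows = []
    for chrom in sorted(expected_markers):
        pls = sorted(
            (p for p in placements if p.ref_chrom == chrom), key=lambda p: p.ref_start
        )
        expected = expected_markers[chrom]
        placed = len(pls)
        on_primary = sum(1 for p in pls if p.subject_id == primary.get(chrom))
        unamb = [p.subject_start for p in pls if not p.ambiguous]
        coll = lis_length(unamb) / len(unamb) if unamb else 0.0
        rows.append(
            {
                "chrom": chrom,
                "expected_markers": expected,
                "placed": placed,
                "recovery": placed / expected if expected else 0.0,
                "primary_placed": on_primary,
                "primary_recovery": on_primary / expected if expected else 0.0,
                "collinearity": coll,
            }
        )
    return pd.DataFrame(rows).set_index("chrom")
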