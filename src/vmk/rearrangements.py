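"""Call large inversions and translocations from marker order.

An inversion is read off as an anti-diagonal run: a collinear block whose
normalized strand is minus.  A translocation is a run of reference
markers whose best placements sit on a scaffold assigned to a different
chromosome.  Breakpoints are reported snapped to the marker grid — the
interval runs from the first supporting marker's start to one grid step
past the last one, in ``k*s + 1`` form — so the true breakpoints lie
within one grid step of each reported endpoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .comparative import CollinearBlock, ScaffoldAssignment
from .mapping import PlacedMarker

__all__ = [
    "RearrangementCall",
    "GenotypeMatrix",
    "call_inversions",
    "call_translocations",
    "guaranteed_detectable_length",
    "span_support",
    "genotype_matrix",
]


@dataclass(frozen=True)
class RearrangementCall:
    """One inversion or translocation with a grid-snapped interval.

    ``start``/``end`` are 1-based inclusive on the reference and both of
    the form ``k*spacing + 1``; the true breakpoints lie within one grid
    step of each endpoint.
    """

    type: str
    chrom: str
    start: int
    end: int
    n_markers: int
    subject_id: str
    assembly_label: str = ""

    @property
    def region(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _snap_interval(ref_first: int, ref_last: int, spacing: int) -> tuple[int, int]:
    # 0-based marker starts -> 1-based inclusive grid interval
    return ref_first + 1, ref_last + spacing + 1


def call_inversions(
    blocks: Sequence[CollinearBlock],
    spacing: int,
    min_markers: int = 2,
    assembly_label: str = "",
) -> list[RearrangementCall]:
    """Every minus block supported by >= ``min_markers`` becomes a call.

    Blocks must come from orientation-normalized placements, so a wholly
    reverse-complemented scaffold yields no calls.
    """
    calls = []
    for b in blocks:
        if b.sign == -1 and b.n_markers >= min_markers:
            start, end = _snap_interval(b.ref_first, b.ref_last, spacing)
            calls.append(
                RearrangementCall(
                    type="inversion",
                    chrom=b.chrom,
                    start=start,
                    end=end,
                    n_markers=b.n_markers,
                    subject_id=b.subject_id,
                    assembly_label=assembly_label,
                )
            )
    return calls


def call_translocations(
    placements: Sequence[PlacedMarker],
    assignments: Sequence[ScaffoldAssignment],
    spacing: int,
    min_markers: int = 2,
    assembly_label: str = "",
) -> list[RearrangementCall]:
    """Call runs of markers landing on a scaffold of another chromosome.

    Maximal runs of consecutive (reference-ordered, unambiguous) markers
    whose best hits share one foreign-assigned scaffold, with at least
    ``min_markers`` members, are reported with the same grid-snapping as
    inversions.
    """
    assigned_chrom = {a.subject_id: a.chrom for a in assignments}
    usable = sorted(
        (p for p in placements if not p.ambiguous),
        key=lambda p: (p.ref_chrom, p.ref_start),
    )
    calls: list[RearrangementCall] = []
    run: list[PlacedMarker] = []

    def flush() -> None:
        if len(run) >= min_markers:
            start, end = _snap_interval(run[0].ref_start, run[-1].ref_start, spacing)
            calls.append(
                RearrangementCall(
                    type="translocation",
                    chrom=run[0].ref_chrom,
                    start=start,
                    end=end,
                    n_markers=len(run),
                    subject_id=run[0].subject_id,
                    assembly_label=assembly_label,
                )
            )

    for p in usable:
        foreign = assigned_chrom.get(p.subject_id, p.ref_chrom) != p.ref_chrom
        if (
            foreign
            and run
            and run[-1].ref_chrom == p.ref_chrom
            and run[-1].subject_id == p.subject_id
        ):
            run.append(p)
        else:
            flush()
            run = [p] if foreign else []
    flush()
    return calls


def guaranteed_detectable_length(spacing: int, marker_len: int, min_markers: int = 2) -> int:
    """Smallest length guaranteed to contain ``min_markers`` full markers.

    Markers of length m sit at grid starts 0, s, 2s, ...  An interval of
    length L starting at offset a fully contains marker i iff
    ``i*s >= a`` and ``i*s + m <= a + L``.  This returns the minimum L
    such that *every* offset a in [0, s) contains at least
    ``min_markers`` full markers — i.e. the length above which an
    inversion or translocation can never hide from the grid.  Computed by
    brute force over all s offsets (vectorized), with a binary search
    over L, which is exact because containment is monotone in L.
    """
    if marker_len < 1 or spacing <= marker_len:
        raise ValueError("need spacing > marker_len >= 1")
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    s, m, k = spacing, marker_len, min_markers
    a = np.arange(s, dtype=np.int64)
    first = (a + s - 1) // s  # smallest i with i*s >= a

    def ok(L: int) -> bool:
        last = (a + L - m) // s  # largest i with i*s + m <= a + L
        return bool(np.all(last - first + 1 >= k))

    lo, hi = m - 1, k * s + m  # lo fails, hi must succeed
    if not ok(hi):  # pragma: no cover - defensive; hi = k*s + m always works
        raise RuntimeError("internal error: search upper bound too small")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi


def span_support(
    alignments: Iterable[tuple], breakpoint: int, flank: int = 10_000
) -> int:
    """Count read alignments spanning ``breakpoint`` by >= ``flank`` on both sides.

    ``alignments`` are (start, end) or (name, start, end) intervals of
    read-to-reference alignments on the breakpoint's chromosome; both
    boundary comparisons are inclusive.  Few or no spanning reads across
    a putative inversion breakpoint corroborate the call.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    n = 0
    for iv in alignments:
        start, end = (iv[1], iv[2]) if len(iv) >= 3 else (iv[0], iv[1])
        if start <= breakpoint - flank and end >= breakpoint + flank:
            n += 1
    return n


@dataclass
class GenotypeMatrix:
    """Presence/absence of merged rearrangement loci across assemblies."""

    loci: list[RearrangementCall] = field(default_factory=list)
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def _reciprocal_overlap(a: RearrangementCall, b: RearrangementCall) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def genotype_matrix(
    calls_by_assembly: Mapping[str, Sequence[RearrangementCall]],
    reciprocal_overlap: float = 0.8,
) -> GenotypeMatrix:
    """Merge calls across assemblies into loci and tabulate presence.

    Calls of the same type on the same chromosome are single-linkage
    merged when their reciprocal overlap reaches the threshold; each
    merged locus spans the union of its contributing calls.  The frame
    has loci as rows (``type:chrom:start-end``) and assembly labels as
    columns, in the order given.
    """
    if not calls_by_assembly:
        raise ValueError("need at least one assembly")
    labels = list(calls_by_assembly)
    flat: list[tuple[str, RearrangementCall]] = [
        (label, c) for label in labels for c in calls_by_assembly[label]
    ]
    n = len(flat)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = flat[i][1], flat[j][1]
            if a.type == b.type and a.chrom == b.chrom:
                if _reciprocal_overlap(a, b) >= reciprocal_overlap:
                    parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    loci: list[RearrangementCall] = []
    rows: list[dict] = []
    for members in groups.values():
        calls = [flat[i][1] for i in members]
        locus = RearrangementCall(
            type=calls[0].type,
            chrom=calls[0].chrom,
            start=min(c.start for c in calls),
            end=max(c.end for c in calls),
            n_markers=max(c.n_markers for c in calls),
            subject_id="",
            assembly_label="",
        )
        present = {flat[i][0] for i in members}
        loci.append(locus)
        rows.append({label: (label in present) for label in labels})

    order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].start, loci[i].type))
    loci = [loci[i] for i in order]
    frame = pd.DataFrame(
        [rows[i] for i in order],
        index=[f"{l.type}:{l.region}" for l in loci],
        columns=labels,
        dtype=bool,
    )
    frame.index.name = "locus"
    return GenotypeMatrix(loci=loci, frame=frame)
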