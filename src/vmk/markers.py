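"""Virtual marker generation.

A virtual marker is a short subsequence (default 2 kb) cut from a
reference chromosome at fixed grid positions (default every 1 Mb,
anchored at the first base).  Mapping these markers onto an assembly and
reading off their order and strand turns whole-genome comparison into a
cheap, grid-resolution dot-plot problem: diagonal runs mean collinearity,
anti-diagonal runs mean inversion, and runs landing on a scaffold
assigned to another chromosome mean translocation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from .io_formats import SequenceRecord, read_sequences, write_sequences

logger = logging.getLogger(__name__)

__all__ = ["MarkerSetSpec", "Marker", "MarkerSet", "generate_markers", "parse_marker_id"]


@dataclass(frozen=True)
class MarkerSetSpec:
    """Geometry of a marker grid.

    spacing
        Distance between consecutive marker start positions, bp.  The
        default 1 Mb corresponds to the low-resolution genome-wide set; a
        100-kb spacing gives the high-resolution set used for breakpoint
        work.
    marker_len
        Length of each marker, bp (default 2 kb).
    max_ambiguous_frac
        Grid windows whose fraction of N exceeds this are skipped, so
        markers are never cut from assembly gaps.
    """

    spacing: int = 1_000_000
    marker_len: int = 2_000
    max_ambiguous_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.spacing < 1_000:
            raise ValueError(f"spacing must be >= 1000 bp, got {self.spacing}")
        if not self.marker_len < self.spacing:
            raise ValueError("marker_len must be smaller than spacing")
        if not 0.0 <= self.max_ambiguous_frac <= 1.0:
            raise ValueError("max_ambiguous_frac must be within [0, 1]")


@dataclass(frozen=True)
class Marker:
    """One virtual marker; ``start`` is 0-based on the reference."""

    chrom: str
    start: int
    seq: str

    @property
    def id(self) -> str:
        # ids carry the 1-based start so they read like genome coordinates
        return f"{self.chrom}_{self.start + 1}"


def parse_marker_id(marker_id: str) -> tuple[str, int]:
    """Recover (chrom, 0-based start) from a ``{chrom}_{start1}`` id."""
    chrom, _, start1 = marker_id.rpartition("_")
    if not chrom:
        raise ValueError(f"not a marker id: {marker_id!r}")
    try:
        start = int(start1) - 1
    except ValueError:
        raise ValueError(f"not a marker id: {marker_id!r}") from None
    if start < 0:
        raise ValueError(f"not a marker id: {marker_id!r}")
    return chrom, start


@dataclass
class MarkerSet:
    """An ordered collection of markers sharing one grid geometry."""

    spec: MarkerSetSpec
    markers: list[Marker] = field(default_factory=list)

    def __iter__(self) -> Iterator[Marker]:
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def count_by_chrom(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for mk in self.markers:
            counts[mk.chrom] = counts.get(mk.chrom, 0) + 1
        return counts

    def to_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(mk.id, mk.seq) for mk in self.markers]

    def write_fasta(self, path: str | Path) -> Path:
        return write_sequences(self.to_records(), path)

    @classmethod
    def from_fasta(cls, path: str | Path, spec: MarkerSetSpec) -> "MarkerSet":
        markers = []
        for rec in read_sequences(path):
            chrom, start = parse_marker_id(rec.id)
            markers.append(Marker(chrom, start, rec.seq))
        return cls(spec=spec, markers=markers)


def generate_markers(
    reference: Sequence[SequenceRecord], spec: MarkerSetSpec | None = None
) -> MarkerSet:
    """Cut a marker set from a reference genome.

    Candidate windows start at 0-based positions 0, s, 2s, ... (1-based
    1, s+1, 2s+1, ...) and must fit entirely inside the chromosome.
    Windows with more than ``max_ambiguous_frac`` N are skipped.
    Chromosomes shorter than one marker are skipped with a warning.
    """
    spec = spec or MarkerSetSpec()
    s, m = spec.spacing, spec.marker_len
    max_n = spec.max_ambiguous_frac * m
    out: list[Marker] = []
    for rec in reference:
        if len(rec.seq) < m:
            logger.warning(
                "chromosome %s (%d bp) is shorter than one marker (%d bp); skipped",
                rec.id,
                len(rec.seq),
                m,
            )
            continue
        for start in range(0, len(rec.seq) - m + 1, s):
            window = rec.seq[start : start + m]
            if window.count("N") > max_n:
                continue
            out.append(Marker(rec.id, start, window))
    return MarkerSet(spec=spec, markers=out)
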