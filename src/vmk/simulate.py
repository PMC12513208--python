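"""Synthetic genomes with planted rearrangements and known truth.

This generator produces everything the rest of the toolkit needs to be
tested end to end at desk scale: random multi-chromosome genomes,
planted inversions/translocations/deletions with a serializable truth
set, substitution noise, scaffold fragmentation re-joined with fixed-
length N gaps (the convention of Hi-C scaffolders, which separate
adjacent contigs with exactly 100 N), and uniformly drawn long reads.

Truth coordinates are recorded on the unedited reference frame, the same
frame in which rearrangement calls are reported, so planted events and
calls compare directly.  Edits and read errors are substitution-only so
the built-in exact matcher remains an appropriate read-back instrument;
indel realism is delegated to external aligners.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import SequenceRecord, reverse_complement

__all__ = [
    "EditSpec",
    "TruthSet",
    "random_genome",
    "apply_edits",
    "add_substitutions",
    "fragment_and_scaffold",
    "simulate_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class EditSpec:
    """One planted edit, 1-based inclusive on the unedited reference.

    ``type`` is one of ``inversion``, ``deletion``, ``translocation``;
    translocations excise [start, end] from ``chrom`` and reinsert it so
    that it begins at original coordinate ``dest_pos`` of ``dest_chrom``.
    """

    type: str
    chrom: str
    start: int
    end: int
    dest_chrom: str | None = None
    dest_pos: int | None = None

    def __post_init__(self) -> None:
        if self.type not in {"inversion", "deletion", "translocation"}:
            raise ValueError(f"unknown edit type {self.type!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad edit interval {self.start}..{self.end}")
        if self.type == "translocation" and (self.dest_chrom is None or self.dest_pos is None):
            raise ValueError("translocation needs dest_chrom and dest_pos")

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open source interval."""
        return self.start - 1, self.end


@dataclass
class TruthSet:
    """Ground truth of one simulated assembly; JSON round-trippable."""

    edits: list[EditSpec] = field(default_factory=list)
    seed: int | None = None
    substitution_rate: float = 0.0
    breaks: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "edits": [asdict(e) for e in self.edits],
            "seed": self.seed,
            "substitution_rate": self.substitution_rate,
            "breaks": self.breaks,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            edits=[EditSpec(**e) for e in payload["edits"]],
            seed=payload.get("seed"),
            substitution_rate=payload.get("substitution_rate", 0.0),
            breaks={k: list(v) for k, v in payload.get("breaks", {}).items()},
        )


def random_genome(
    chrom_lengths: Sequence[int],
    gc: float = 0.41,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> list[SequenceRecord]:
    """I.i.d. random chromosomes at the given GC content (default 0.41,
    the human genome-wide value). Deterministic for a fixed seed."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    at, gch = (1.0 - gc) / 2.0, gc / 2.0
    cum = np.cumsum([at, gch, gch, at])  # A C G T
    if names is None:
        names = [f"chr{i + 1}" for i in range(len(chrom_lengths))]
    records = []
    for name, L in zip(names, chrom_lengths):
        draws = _BASES[np.searchsorted(cum, rng.random(int(L)), side="right")]
        records.append(SequenceRecord(name, draws.tobytes().decode("ascii")))
    return records


def _check_edits(genome_lengths: Mapping[str, int], edits: Sequence[EditSpec]) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for e in edits:
        if e.chrom not in genome_lengths:
            raise ValueError(f"edit on unknown chromosome {e.chrom!r}")
        if e.end > genome_lengths[e.chrom]:
            raise ValueError(f"edit {e} exceeds chromosome length")
        by_chrom.setdefault(e.chrom, []).append(e.span)
        if e.type == "translocation":
            if e.dest_chrom not in genome_lengths:
                raise ValueError(f"translocation destination {e.dest_chrom!r} unknown")
    for chrom, spans in by_chrom.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping edits on {chrom}: {s1}-{e1} and {s2}-{e2}")


def apply_edits(
    genome: Sequence[SequenceRecord], edits: Sequence[EditSpec]
) -> tuple[list[SequenceRecord], TruthSet]:
    """Apply non-overlapping edits, returning the edited genome and truth.

    Inversions replace the segment with its reverse complement in place;
    deletions remove it; translocations excise the segment and reinsert
    it at the destination (whose coordinate refers to the unedited
    destination chromosome).  Applying the same inversion twice restores
    the original sequence.
    """
    seqs = {r.id: r.seq for r in genome}
    order = [r.id for r in genome]
    _check_edits({k: len(v) for k, v in seqs.items()}, edits)

    # 1) inversions: in place, no coordinate shift
    for e in edits:
        if e.type == "inversion":
            s0, e0 = e.span
            seq = seqs[e.chrom]
            seqs[e.chrom] = seq[:s0] + reverse_complement(seq[s0:e0]) + seq[e0:]

    # 2) excisions (deletions and translocation sources), right to left
    removed: dict[str, list[tuple[int, int]]] = {}
    segments: list[tuple[EditSpec, str]] = []
    for e in sorted(
        (e for e in edits if e.type in {"deletion", "translocation"}),
        key=lambda e: (e.chrom, -e.start),
    ):
        s0, e0 = e.span
        seq = seqs[e.chrom]
        if e.type == "translocation":
            segments.append((e, seq[s0:e0]))
        seqs[e.chrom] = seq[:s0] + seq[e0:]
        removed.setdefault(e.chrom, []).append((s0, e0))

    # 3) insertions; destination coordinates shift by whatever was excised
    #    before them, and later insertions into the same chromosome are
    #    applied right to left so they do not displace each other
    def adjusted_dest(e: EditSpec) -> int:
        pos0 = e.dest_pos - 1
        for s0, e0 in removed.get(e.dest_chrom, []):
            if e0 <= pos0:
                pos0 -= e0 - s0
            elif s0 < pos0 < e0:
                raise ValueError(
                    f"translocation destination {e.dest_chrom}:{e.dest_pos} "
                    "falls inside an excised interval"
                )
        return pos0

    for e, segment in sorted(segments, key=lambda t: -adjusted_dest(t[0])):
        pos0 = adjusted_dest(e)
        seq = seqs[e.dest_chrom]
        if pos0 > len(seq):
            raise ValueError(
                f"translocation destination {e.dest_chrom}:{e.dest_pos} beyond chromosome end"
            )
        seqs[e.dest_chrom] = seq[:pos0] + segment + seq[pos0:]

    edited = [SequenceRecord(name, seqs[name]) for name in order]
    return edited, TruthSet(edits=list(edits))


def add_substitutions(
    genome: Sequence[SequenceRecord], rate: float = 0.001, seed: int = 0
) -> list[SequenceRecord]:
    """Sprinkle random substitutions at the given per-base rate.

    Substituted bases always change to a different ACGT base; N positions
    are left untouched.  The default rate of 0.1% is on the scale of
    SNV divergence between two human individuals.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for rec in genome:
        code = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8).copy()
        n = rng.binomial(len(code), rate)
        if n == 0:
            out.append(rec)
            continue
        pos = rng.choice(len(code), size=n, replace=False)
        # map A,C,G,T -> 0..3; rotate by 1..3 to guarantee a change
        lut = np.full(256, 255, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        old = lut[code[pos]]
        editable = old != 255
        pos = pos[editable]
        old = old[editable]
        shift = rng.integers(1, 4, size=old.size)
        code[pos] = _BASES[(old + shift) % 4]
        out.append(SequenceRecord(rec.id, code.tobytes().decode("ascii")))
    return out


def fragment_and_scaffold(
    genome: Sequence[SequenceRecord],
    breaks: Mapping[str, Sequence[int]],
    gap_len: int = 100,
) -> list[SequenceRecord]:
    """Split chromosomes at break offsets and re-join with N gaps.

    A break at offset b (0 < b < length) cuts between ``seq[:b]`` and
    ``seq[b:]``; the pieces are re-joined with runs of exactly
    ``gap_len`` N, so each scaffold grows by ``gap_len * n_breaks`` bp.
    """
    out = []
    for rec in genome:
        cuts = sorted(set(breaks.get(rec.id, ())))
        for b in cuts:
            if not 0 < b < len(rec.seq):
                raise ValueError(f"break {b} not strictly inside {rec.id}")
        bounds = [0, *cuts, len(rec.seq)]
        pieces = [rec.seq[a:b] for a, b in zip(bounds, bounds[1:])]
        joined = ("N" * gap_len).join(pieces)
        out.append(SequenceRecord(f"{rec.id}_scaffold", joined))
    return out


def simulate_reads(
    genome: Sequence[SequenceRecord],
    coverage: float,
    read_len_mean: int = 15_000,
    error_rate: float = 0.001,
    seed: int = 0,
    path: str | Path | None = None,
) -> list[tuple[str, str, str]]:
    """Draw uniform long reads until total bases reach coverage x genome.

    Reads come from either strand of a length-weighted random chromosome,
    with normally distributed lengths (sd = 10% of the mean) and i.i.d.
    substitution errors.  Returns ``(id, sequence, quality)`` triples and
    optionally writes a FASTQ file.  Deterministic for a fixed seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    ids = [r.id for r in genome]
    lengths = np.array([len(r) for r in genome], dtype=float)
    weights = lengths / lengths.sum()
    seqs = {r.id: r.seq for r in genome}
    target = coverage * lengths.sum()

    reads: list[tuple[str, str, str]] = []
    total = 0
    i = 0
    while total < target:
        chrom = ids[rng.choice(len(ids), p=weights)]
        L = len(seqs[chrom])
        rl = int(rng.normal(read_len_mean, 0.1 * read_len_mean))
        rl = max(100, min(rl, L))
        start = int(rng.integers(0, L - rl + 1))
        frag = seqs[chrom][start : start + rl]
        if rng.random() < 0.5:
            frag = reverse_complement(frag)
        if error_rate > 0:
            frag = add_substitutions(
                [SequenceRecord("r", frag)], rate=error_rate, seed=int(rng.integers(2**31))
            )[0].seq
        reads.append((f"read{i}", frag, "I" * len(frag)))
        total += len(frag)
        i += 1

    if path is not None:
        with open(path, "w") as fh:
            for rid, seq, qual in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return reads
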