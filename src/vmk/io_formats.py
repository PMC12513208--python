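"""Readers and writers for the plain-text formats the toolkit exchanges.

Every in-memory coordinate in this package is 0-based half-open.  Every
file written or read here uses the conventions of its format — BLAST
tabular and the human-readable ``chrN:start-end`` region strings are
1-based inclusive, the calls file is BED-like (0-based half-open start,
end column equal to the 1-based inclusive end) — and the conversion
between the two happens in this module only.

Supported formats: FASTA (optionally gzipped), FASTQ, BLAST tabular
``outfmt 6`` (12 tab-separated columns), a 12-column PAF subset, and the
toolkit's own TSVs for rearrangement calls and marker placements.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "AlignmentRow",
    "reverse_complement",
    "read_sequences",
    "write_sequences",
    "read_alignment_table",
    "write_alignment_table",
    "write_calls",
    "read_calls",
    "write_placements",
    "read_placements",
]

# any byte that is not A, C, G, T or N becomes N (IUPAC codes, gaps, ...)
_CLEAN_TABLE = bytearray(b"N" * 256)
for _b in b"ACGTN":
    _CLEAN_TABLE[_b] = _b
_CLEAN_TABLE = bytes(_CLEAN_TABLE)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentRow:
    """One query-to-subject alignment in BLAST outfmt-6 terms.

    Coordinates are 1-based inclusive as printed by BLAST; a subject
    interval with ``s_start > s_end`` encodes the minus strand.
    """

    query_id: str
    subject_id: str
    pident: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident out of range: {self.pident}")
        if self.aln_len < 1:
            raise ValueError(f"aln_len must be >= 1, got {self.aln_len}")
        if min(self.q_start, self.q_end, self.s_start, self.s_end) < 1:
            raise ValueError("alignment coordinates must be >= 1")

    @property
    def strand(self) -> str:
        return "+" if self.s_start <= self.s_end else "-"

    @property
    def subject_left(self) -> int:
        """0-based leftmost subject position of the alignment."""
        return min(self.s_start, self.s_end) - 1

    @property
    def subject_right(self) -> int:
        """0-based exclusive right end of the alignment on the subject."""
        return max(self.s_start, self.s_end)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _clean_seq(raw: str) -> str:
    return raw.upper().encode("ascii").translate(_CLEAN_TABLE).decode("ascii")


def read_sequences(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file.

    Sequences are uppercased and any non-ACGTN character is mapped to N.
    Raises ``ValueError`` on an empty file or a duplicate record id.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = _clean_seq(str(rec.seq))
            if not seq:
                raise ValueError(f"record {rec.id!r} in {path} has empty sequence")
            records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> Path:
    """Write records as FASTA (gzipped when the path ends in .gz)."""
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# alignment tables


def _parse_blast6(fields: list[str], lineno: int, path) -> AlignmentRow:
    # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore
    return AlignmentRow(
        query_id=fields[0],
        subject_id=fields[1],
        pident=float(fields[2]),
        aln_len=int(fields[3]),
        q_start=int(fields[6]),
        q_end=int(fields[7]),
        s_start=int(fields[8]),
        s_end=int(fields[9]),
        bitscore=float(fields[11]),
    )


def _parse_paf(fields: list[str], lineno: int, path) -> AlignmentRow:
    # qname qlen qstart qend strand tname tlen tstart tend matches blocklen mapq
    strand = fields[4]
    if strand not in {"+", "-", "−"}:  # tolerate a typographic minus
        raise ValueError(f"{path}:{lineno}: bad PAF strand {strand!r}")
    q_start0, q_end = int(fields[2]), int(fields[3])
    t_start0, t_end = int(fields[7]), int(fields[8])
    matches, block_len = int(fields[9]), int(fields[10])
    if block_len < 1:
        raise ValueError(f"{path}:{lineno}: PAF block length must be >= 1")
    if strand == "+":
        s_start, s_end = t_start0 + 1, t_end
    else:
        s_start, s_end = t_end, t_start0 + 1
    return AlignmentRow(
        query_id=fields[0],
        subject_id=fields[5],
        pident=100.0 * matches / block_len,
        aln_len=block_len,
        q_start=q_start0 + 1,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        bitscore=float(matches),
    )


_DIALECTS = {"blast6": _parse_blast6, "paf": _parse_paf}


def read_alignment_table(path: str | Path, dialect: str = "blast6") -> list[AlignmentRow]:
    """Parse a 12-column BLAST outfmt-6 table or the first 12 PAF columns.

    PAF identity is computed as matches / block length x 100; minus-strand
    PAF records are normalized into the blast6 ``s_start > s_end``
    convention.  A line with fewer than 12 columns raises ``ValueError``
    naming the line number.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    parse = _DIALECTS[dialect]
    rows: list[AlignmentRow] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns, got {len(fields)}"
                )
            rows.append(parse(fields, lineno, path))
    return rows


def write_alignment_table(rows: Iterable[AlignmentRow], path: str | Path) -> Path:
    """Write rows in BLAST outfmt-6 column order (12 columns)."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in rows:
            mismatch = r.aln_len - round(r.pident * r.aln_len / 100.0)
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        f"{r.pident:.3f}",
                        str(r.aln_len),
                        str(mismatch),
                        "0",
                        str(r.q_start),
                        str(r.q_end),
                        str(r.s_start),
                        str(r.s_end),
                        "0.0",
                        f"{r.bitscore:.1f}",
                    ]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# rearrangement calls

_CALL_HEADER = "#chrom\tstart\tend\ttype\tn_markers\tsubject\tassembly\tregion"


def write_calls(calls: Iterable, path: str | Path) -> Path:
    """Write rearrangement calls as a BED-like TSV.

    ``start`` is 0-based half-open, ``end`` equals the 1-based inclusive
    endpoint, and ``region`` is the 1-based ``chrN:start-end`` string used
    in reports.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_CALL_HEADER + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.type}\t{c.n_markers}"
                f"\t{c.subject_id}\t{c.assembly_label}\t{c.region}\n"
            )
    return path


def read_calls(path: str | Path) -> list:
    """Read a calls TSV written by :func:`write_calls`."""
    from .rearrangements import RearrangementCall

    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns, got {len(f)}")
            calls.append(
                RearrangementCall(
                    type=f[3],
                    chrom=f[0],
                    start=int(f[1]) + 1,
                    end=int(f[2]),
                    n_markers=int(f[4]),
                    subject_id=f[5],
                    assembly_label=f[6],
                )
            )
    return calls


# ---------------------------------------------------------------------------
# marker placements

_PLACEMENT_HEADER = (
    "#marker_id\tref_chrom\tref_start\tsubject\tsubject_start\tsubject_end"
    "\tstrand\tpident\tambiguous"
)


def write_placements(placements: Iterable, path: str | Path) -> Path:
    """Write best-hit marker placements as TSV (1-based inclusive spans)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_PLACEMENT_HEADER + "\n")
        for p in placements:
            fh.write(
                f"{p.marker_id}\t{p.ref_chrom}\t{p.ref_start + 1}\t{p.subject_id}"
                f"\t{p.subject_start + 1}\t{p.subject_end}\t{p.strand}"
                f"\t{p.pident:.3f}\t{int(p.ambiguous)}\n"
            )
    return path


def read_placements(path: str | Path) -> list:
    """Read a placements TSV written by :func:`write_placements`."""
    from .mapping import PlacedMarker

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(f)}")
            out.append(
                PlacedMarker(
                    marker_id=f[0],
                    ref_chrom=f[1],
                    ref_start=int(f[2]) - 1,
                    subject_id=f[3],
                    subject_start=int(f[4]) - 1,
                    subject_end=int(f[5]),
                    strand=f[6],
                    pident=float(f[7]),
                    ambiguous=bool(int(f[8])),
                )
            )
    return out
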