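"""Place virtual markers on an assembly and filter the hits.

Two placement routes feed the same downstream machinery:

* the built-in matcher (:func:`place_markers`), a substitution-only
  exact-seed search suitable for desk-scale genomes and simulations, and
* imported alignment tables (blast6 / PAF) produced by an external
  aligner, parsed by :mod:`vmk.io_formats`.

Both yield :class:`~vmk.io_formats.AlignmentRow` lists, which are then
identity-filtered (with a per-chromosome longest-scaffold exemption) and
reduced to one best placement per marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AlignmentRow, SequenceRecord, reverse_complement
from .markers import MarkerSet, parse_marker_id

logger = logging.getLogger(__name__)

__all__ = ["PlacedMarker", "place_markers", "filter_hits", "best_hits"]

# base codes: A,C,G,T -> 0..3, anything else -> 4 (treated as never matching)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class PlacedMarker:
    """The selected best placement of one marker on an assembly.

    ``ref_start`` and ``subject_start``/``subject_end`` are 0-based
    half-open.  ``ambiguous`` flags markers whose runner-up hit scored
    within the ambiguity margin of the best hit; such markers are kept
    for dot plots but excluded from rearrangement calling.
    """

    marker_id: str
    ref_chrom: str
    ref_start: int
    subject_id: str
    subject_start: int
    subject_end: int
    strand: str
    pident: float
    ambiguous: bool = False

    @property
    def sign(self) -> int:
        return 1 if self.strand == "+" else -1


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# base-5 hashing (N is a fifth symbol) keeps the encoding injective even
# across gap runs; seed k-mers are N-free, so N windows simply never match
_PRE_K = 8  # prefilter word size; 5**8 fits comfortably in int32


def _rolling_hashes(code: np.ndarray, k: int, dtype=np.int64) -> np.ndarray:
    """Base-5 hash of every k-mer of ``code``.

    Built by binary doubling — a window hash of length a+b is
    ``h_a(i) * 5**b + h_b(i+a)`` — so only O(log k) vector passes are
    needed over the sequence.
    """
    n = code.size
    nwin = n - k + 1
    if nwin <= 0:
        return np.empty(0, dtype=dtype)
    codew = code.astype(dtype)

    def combine(ha: np.ndarray, la: int, hb: np.ndarray, lb: int) -> np.ndarray:
        L = n - (la + lb) + 1
        return ha[:L] * (5**lb) + hb[la : la + L]

    h, cur = codew, 1
    for bit in bin(k)[3:]:  # remaining bits after the leading 1
        h = combine(h, cur, h, cur)
        cur *= 2
        if bit == "1":
            h = combine(h, cur, codew, 1)
            cur += 1
    return h[:nwin]


def _hash_kmer(seq: str) -> int | None:
    """Base-5 hash of a clean seed k-mer; None if it contains non-ACGT."""
    code = _encode(seq)
    if (code >= 4).any():
        return None
    val = 0
    for c in code.tolist():
        val = val * 5 + c
    return val


def place_markers(
    markers: MarkerSet,
    assembly: Sequence[SequenceRecord],
    k: int = 21,
    min_candidate_pident: float = 80.0,
) -> list[AlignmentRow]:
    """Find candidate loci for every marker on every assembly scaffold.

    Seeds are exact k-mers sampled at ~8 evenly spaced offsets within each
    marker, on both strands.  Seed hits sharing a (subject, implied
    offset, strand) are collapsed into one candidate locus, which is then
    scored by ungapped comparison over the full marker length:
    ``pident = matches / marker_len * 100`` (N counts as mismatch).
    Candidates at or above ``min_candidate_pident`` are returned as
    blast6-style rows with ``bitscore`` set to the match count.

    The matcher is substitution-only by design; indel-bearing loci must
    come from an imported aligner.
    """
    if not assembly:
        raise ValueError("assembly must contain at least one sequence")
    if len(markers) == 0:
        return []
    m = markers.spec.marker_len
    if k >= m:
        raise ValueError(f"seed length k={k} must be shorter than the marker ({m} bp)")
    stride = max(1, (m - k) // 7)
    offsets = list(range(0, m - k + 1, stride))

    # seed hash -> [(marker_index, strand, offset_in_oriented_marker)]
    seed_map: dict[int, list[tuple[int, str, int]]] = {}
    oriented: list[dict[str, np.ndarray]] = []
    for mi, mk in enumerate(markers):
        if len(mk.seq) != m:
            raise ValueError(f"marker {mk.id} length {len(mk.seq)} != spec marker_len {m}")
        strands = {"+": mk.seq, "-": reverse_complement(mk.seq)}
        oriented.append({st: _encode(sq) for st, sq in strands.items()})
        for st, sq in strands.items():
            for off in offsets:
                hval = _hash_kmer(sq[off : off + k])
                if hval is None:
                    continue
                seed_map.setdefault(hval, []).append((mi, st, off))
    if not seed_map:
        return []
    keys = np.array(sorted(seed_map), dtype=np.int64)
    # 8-mer prefix membership mask: cheap first pass over the subject
    prefix_mask = np.zeros(5**_PRE_K, dtype=bool)
    div = 5 ** (k - _PRE_K)
    prefix_mask[keys // div] = True

    rows: list[AlignmentRow] = []
    marker_list = list(markers)
    for rec in assembly:
        code = _encode(rec.seq)
        if code.size < k:
            continue
        h8 = _rolling_hashes(code, _PRE_K, dtype=np.int32)
        nwin = code.size - k + 1
        cand_pos = np.nonzero(prefix_mask[h8[:nwin]])[0]
        if cand_pos.size == 0:
            continue
        # full-length hash only at prefiltered positions
        full = np.zeros(cand_pos.size, dtype=np.int64)
        for j in range(k):
            full *= 5
            full += code[cand_pos + j]
        idx = np.searchsorted(keys, full)
        np.clip(idx, 0, keys.size - 1, out=idx)
        matched = keys[idx] == full
        candidates: set[tuple[int, str, int]] = set()
        L = len(rec.seq)
        for pos, hval in zip(cand_pos[matched].tolist(), full[matched].tolist()):
            for mi, st, off in seed_map[hval]:
                start = pos - off
                if 0 <= start <= L - m:
                    candidates.add((mi, st, start))
        for mi, st, start in sorted(candidates):
            q = oriented[mi][st]
            s = code[start : start + m]
            matches = int(np.count_nonzero((q == s) & (q < 4)))
            pident = 100.0 * matches / m
            if pident < min_candidate_pident:
                continue
            if st == "+":
                s_start, s_end = start + 1, start + m
            else:
                s_start, s_end = start + m, start + 1
            rows.append(
                AlignmentRow(
                    query_id=marker_list[mi].id,
                    subject_id=rec.id,
                    pident=pident,
                    aln_len=m,
                    q_start=1,
                    q_end=m,
                    s_start=s_start,
                    s_end=s_end,
                    bitscore=float(matches),
                )
            )
    return rows


def filter_hits(
    rows: Iterable[AlignmentRow],
    min_pident: float = 99.0,
    exempt_subjects: Iterable[str] = (),
) -> list[AlignmentRow]:
    """Keep hits near 100% identity, plus everything on exempt scaffolds.

    The exemption set is meant to hold the per-chromosome longest assigned
    scaffolds: sub-threshold hits there may represent genuine variation
    between individuals rather than mismapping, so they are retained.
    """
    exempt = set(exempt_subjects)
    return [r for r in rows if r.pident >= min_pident or r.subject_id in exempt]


def best_hits(
    rows: Sequence[AlignmentRow],
    score: str = "bitscore",
    ambiguity_margin: float = 0.02,
) -> list[PlacedMarker]:
    """Reduce filtered hits to one placement per marker.

    ``score="bitscore"`` ranks by bitscore (use for imported aligner
    output); ``score="identity"`` ranks by pident then alignment length
    (the built-in matcher's rows).  Ties are broken by smallest subject
    start, then lexicographic subject id, so selection is deterministic.
    A marker is flagged ambiguous when the runner-up's score is within
    ``ambiguity_margin`` (relative) of the best score.
    """
    if score not in {"bitscore", "identity"}:
        raise ValueError(f"unknown score mode {score!r}")

    def primary(r: AlignmentRow) -> float:
        return r.bitscore if score == "bitscore" else r.pident

    groups: dict[str, list[AlignmentRow]] = {}
    for r in rows:
        groups.setdefault(r.query_id, []).append(r)

    out: list[PlacedMarker] = []
    for qid in sorted(groups):
        ranked = sorted(
            groups[qid],
            key=lambda r: (-primary(r), -r.pident, -r.aln_len, r.subject_left, r.subject_id),
        )
        best = ranked[0]
        ambiguous = False
        if len(ranked) > 1:
            ambiguous = primary(ranked[1]) >= (1.0 - ambiguity_margin) * primary(best)
        chrom, ref_start = parse_marker_id(qid)
        out.append(
            PlacedMarker(
                marker_id=qid,
                ref_chrom=chrom,
                ref_start=ref_start,
                subject_id=best.subject_id,
                subject_start=best.subject_left,
                subject_end=best.subject_right,
                strand=best.strand,
                pident=best.pident,
                ambiguous=ambiguous,
            )
        )
    out.sort(key=lambda p: (p.ref_chrom, p.ref_start))
    n_amb = sum(p.ambiguous for p in out)
    if n_amb:
        logger.info("best_hits: %d/%d markers flagged ambiguous", n_amb, len(out))
    return out
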