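"""Assembly contiguity statistics and seeded coverage subsampling.

N50/L50 follow the standard convention: sort scaffold lengths in
descending order; L50 is the smallest number of scaffolds whose summed
length reaches at least half of the assembly total, and N50 is the
length of the scaffold at that rank.  Under the ">= half" rule a perfect
23-chromosome human assembly lands at L50 8-9, matching how these
numbers are quoted for chromosome-level genomes.

Subsampling emulates a seqtk-style titration: each read is kept
independently with probability ``coverage * genome_size / total_bases``
using a seeded generator, so identical seeds give byte-identical output
and the expected kept base count equals the requested coverage.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .io_formats import SequenceRecord, read_sequences

logger = logging.getLogger(__name__)

__all__ = [
    "AssemblyStats",
    "SubsampleSpec",
    "scaffold_stats",
    "subsample_reads",
    "titration_table",
]


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_bp: int
    n50: int
    l50: int
    n_ambiguous: int
    longest: int


def scaffold_stats(seqs: Sequence[SequenceRecord]) -> AssemblyStats:
    """Contiguity statistics of an assembly (N50, L50, N count)."""
    if not seqs:
        raise ValueError("empty assembly")
    lengths = sorted((len(s) for s in seqs), reverse=True)
    total = sum(lengths)
    acc = 0
    for rank, length in enumerate(lengths, start=1):
        acc += length
        if 2 * acc >= total:
            return AssemblyStats(
                n_scaffolds=len(lengths),
                total_bp=total,
                n50=length,
                l50=rank,
                n_ambiguous=sum(s.seq.count("N") for s in seqs),
                longest=lengths[0],
            )
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class SubsampleSpec:
    """Target coverage relative to a genome size, with a sampling seed."""

    target_coverage: float
    genome_size: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_coverage <= 0:
            raise ValueError(f"target_coverage must be > 0, got {self.target_coverage}")
        if self.genome_size <= 0:
            raise ValueError(f"genome_size must be > 0, got {self.genome_size}")


def _open_fastq(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    return gzip.open(path, mode) if path.suffix == ".gz" else open(path, mode)


def subsample_reads(
    in_path: str | Path, out_path: str | Path, spec: SubsampleSpec
) -> tuple[int, int]:
    """Bernoulli-subsample a FASTQ file to a target coverage.

    Two passes: the first totals the input bases B, the second keeps each
    read with probability ``p = coverage * genome_size / B`` (order
    preserved).  If the input holds fewer bases than the target, a
    warning is logged and every read is kept.  Returns
    ``(reads_kept, bases_kept)``.
    """
    total_bases = 0
    with _open_fastq(in_path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            total_bases += len(rec.seq)
    target = spec.target_coverage * spec.genome_size
    if total_bases < target:
        logger.warning(
            "input has %d bases but %.0f requested (%.1fx of %d bp); keeping all reads",
            total_bases,
            target,
            spec.target_coverage,
            spec.genome_size,
        )
        p = 1.0
    else:
        p = target / total_bases

    rng = np.random.default_rng(spec.seed)
    kept = bases = 0
    with _open_fastq(in_path) as fin, _open_fastq(out_path, "wt") as fout:
        for rec in SeqIO.parse(fin, "fastq"):
            if rng.random() < p:
                SeqIO.write(rec, fout, "fastq")
                kept += 1
                bases += len(rec.seq)
    return kept, bases


def titration_table(
    replicate_contig_sets: Mapping[float, Sequence[str | Path]]
) -> pd.DataFrame:
    """Aggregate contiguity statistics across a coverage titration.

    Input maps each coverage to the FASTA paths of its replicate
    assemblies (produced by any external assembler).  Output: one row per
    coverage with mean and standard deviation (population, so a single
    replicate reports sd 0) of N50, L50 and total size.
    """
    rows = []
    for coverage in sorted(replicate_contig_sets):
        stats = [
            scaffold_stats(read_sequences(p)) for p in replicate_contig_sets[coverage]
        ]
        if not stats:
            raise ValueError(f"coverage {coverage}: no replicate assemblies given")
        n50 = np.array([s.n50 for s in stats], dtype=float)
        l50 = np.array([s.l50 for s in stats], dtype=float)
        total = np.array([s.total_bp for s in stats], dtype=float)
        rows.append(
            {
                "coverage": coverage,
                "n_replicates": len(stats),
                "n50_mean": n50.mean(),
                "n50_sd": n50.std(ddof=0),
                "l50_mean": l50.mean(),
                "l50_sd": l50.std(ddof=0),
                "total_bp_mean": total.mean(),
                "total_bp_sd": total.std(ddof=0),
            }
        )
    return pd.DataFrame(rows).set_index("coverage")
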