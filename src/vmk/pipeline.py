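"""End-to-end orchestration: markers -> map -> filter -> assign -> blocks
-> call -> plot -> report, over one or many assemblies.

The longest-scaffold identity-filter exemption is resolved by a two-pass
scheme: pass 1 filters at ``min_pident`` and assigns scaffolds; pass 2
re-admits sub-threshold hits on each chromosome's primary (longest
assigned) scaffold and recomputes placements from the enlarged hit set.
The whole pipeline is a pure function of (inputs, config): repeated runs
produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .assembly_metrics import scaffold_stats
from .comparative import (
    assign_scaffolds,
    linearity_metrics,
    orient_placements,
    segment_blocks,
)
from .io_formats import (
    read_alignment_table,
    read_sequences,
    write_alignment_table,
    write_calls,
    write_placements,
)
from .mapping import best_hits, filter_hits, place_markers
from .markers import MarkerSet, MarkerSetSpec, generate_markers
from .rearrangements import call_inversions, call_translocations, genotype_matrix
from .viz import dotplot_points, render

logger = logging.getLogger(__name__)

__all__ = ["AssemblyInput", "RunConfig", "run_compare"]


@dataclass(frozen=True)
class AssemblyInput:
    """One assembly to compare: FASTA plus optional precomputed alignments."""

    label: str
    path: str
    alignments: str | None = None  # precomputed marker-vs-assembly table
    dialect: str = "blast6"


@dataclass
class RunConfig:
    """Everything a comparison run depends on; serialized next to outputs."""

    reference: str
    assemblies: list[AssemblyInput]
    outdir: str
    spacing: int = 1_000_000
    marker_len: int = 2_000
    max_ambiguous_frac: float = 0.2
    min_pident: float = 99.0
    min_markers: int = 2
    gap_tol: int = 3
    merge_overlap: float = 0.8
    ambiguity_margin: float = 0.02
    seed_len: int = 21
    stacked_y_offset: int = 5_000_000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["assemblies"] = [
            a if isinstance(a, AssemblyInput) else AssemblyInput(**a)
            for a in d["assemblies"]
        ]
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def marker_spec(self) -> MarkerSetSpec:
        return MarkerSetSpec(
            spacing=self.spacing,
            marker_len=self.marker_len,
            max_ambiguous_frac=self.max_ambiguous_frac,
        )


def _check_inputs(config: RunConfig) -> None:
    missing = [p for p in [config.reference] if not Path(p).exists()]
    for a in config.assemblies:
        if not Path(a.path).exists():
            missing.append(a.path)
        if a.alignments and not Path(a.alignments).exists():
            missing.append(a.alignments)
    if missing:
        raise FileNotFoundError(f"missing input file(s): {', '.join(map(str, missing))}")
    labels = [a.label for a in config.assemblies]
    if len(set(labels)) != len(labels):
        raise ValueError("assembly labels must be unique")


def _write_assignments(assignments, path: Path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(a) for a in assignments],
        columns=["subject_id", "chrom", "n_support", "orientation", "is_primary", "length"],
    ).to_csv(path, sep="\t", index=False)


def _write_blocks(blocks, spacing: int, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "subject_id": b.subject_id,
                "sign": b.sign,
                "ref_start": b.ref_first + 1,
                "ref_end": b.ref_last + spacing + 1,
                "subject_start": b.subject_min + 1,
                "subject_end": b.subject_max,
                "n_markers": b.n_markers,
            }
            for b in blocks
        ],
        columns=[
            "chrom",
            "subject_id",
            "sign",
            "ref_start",
            "ref_end",
            "subject_start",
            "subject_end",
            "n_markers",
        ],
    ).to_csv(path, sep="\t", index=False)


def run_compare(config: RunConfig) -> Path:
    """Run the full comparison and write one directory per assembly.

    Per assembly: kept hits (blast6 order), best-hit placements, scaffold
    assignments, collinear blocks, rearrangement calls, per-chromosome
    linearity metrics, and dot-plot points + image.  Across assemblies: a
    genotype matrix of merged loci, a stacked dot plot, and a manifest
    recording version, parameters, and per-assembly summary counts.
    """
    _check_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reference = read_sequences(config.reference)
    marker_set = generate_markers(reference, config.marker_spec())
    expected = marker_set.count_by_chrom()
    logger.info("generated %d markers from %d chromosomes", len(marker_set), len(reference))

    calls_by_assembly: dict[str, list] = {}
    all_points = []
    manifest_assemblies = []
    for asm in config.assemblies:
        adir = outdir / asm.label
        adir.mkdir(exist_ok=True)
        assembly = read_sequences(asm.path)
        lengths = {r.id: len(r) for r in assembly}

        if asm.alignments:
            rows = read_alignment_table(asm.alignments, dialect=asm.dialect)
            score = "bitscore"
        else:
            rows = place_markers(marker_set, assembly, k=config.seed_len)
            score = "identity"

        # pass 1: strict identity filter, provisional assignment
        kept = filter_hits(rows, min_pident=config.min_pident)
        placed = best_hits(kept, score=score, ambiguity_margin=config.ambiguity_margin)
        if not placed:
            logger.warning("%s: no markers placed; skipping", asm.label)
            calls_by_assembly[asm.label] = []
            continue
        assignments = assign_scaffolds(placed, lengths)
        # pass 2: re-admit sub-threshold hits on the primary scaffolds
        exempt = {a.subject_id for a in assignments if a.is_primary}
        kept = filter_hits(rows, min_pident=config.min_pident, exempt_subjects=exempt)
        placed = best_hits(kept, score=score, ambiguity_margin=config.ambiguity_margin)
        assignments = assign_scaffolds(placed, lengths)

        oriented = orient_placements(placed, assignments, lengths)
        blocks = segment_blocks(oriented, config.spacing, gap_tol=config.gap_tol)
        inversions = call_inversions(
            blocks, config.spacing, config.min_markers, assembly_label=asm.label
        )
        translocations = call_translocations(
            oriented, assignments, config.spacing, config.min_markers, assembly_label=asm.label
        )
        calls = inversions + translocations
        calls_by_assembly[asm.label] = calls
        metrics = linearity_metrics(oriented, assignments, expected)

        write_alignment_table(kept, adir / "hits.tsv")
        write_placements(placed, adir / "placements.tsv")
        _write_assignments(assignments, adir / "assignments.tsv")
        _write_blocks(blocks, config.spacing, adir / "blocks.tsv")
        write_calls(calls, adir / "calls.tsv")
        metrics.to_csv(adir / "metrics.tsv", sep="\t")

        points = dotplot_points(kept, assignments, lengths, label=asm.label)
        render(points, adir / "dotplot.png", out_tsv=adir / "dotplot.tsv")
        all_points.append(points)

        stats = scaffold_stats(assembly)
        n_amb = sum(p.ambiguous for p in placed)
        logger.info(
            "%s: %d hits kept, %d markers placed (%d ambiguous), %d calls",
            asm.label,
            len(kept),
            len(placed),
            n_amb,
            len(calls),
        )
        manifest_assemblies.append(
            {
                "label": asm.label,
                "n_scaffolds": stats.n_scaffolds,
                "total_bp": stats.total_bp,
                "n50": stats.n50,
                "l50": stats.l50,
                "hits_kept": len(kept),
                "markers_placed": len(placed),
                "markers_ambiguous": n_amb,
                "n_calls": len(calls),
            }
        )

    matrix = genotype_matrix(calls_by_assembly, reciprocal_overlap=config.merge_overlap)
    matrix.write_tsv(outdir / "genotype_matrix.tsv")

    if all_points:
        combined = pd.concat(all_points, ignore_index=True)
        render(
            combined,
            outdir / "dotplot_stacked.png",
            out_tsv=outdir / "dotplot_stacked.tsv",
            stacked=len(all_points) > 1,
            y_offset=config.stacked_y_offset,
            assembly_order=[a.label for a in config.assemblies],
        )

    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    manifest = {
        "vmk_version": __version__,
        "n_markers": len(marker_set),
        "parameters": config.to_dict(),
        "assemblies": manifest_assemblies,
        "n_loci": len(matrix.loci),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
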