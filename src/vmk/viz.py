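"""Marker dot plots.

The canonical artifact is the points table: one row per kept hit (not
just best hits), with x = the marker's start on the reference and y =
the hit's start on its scaffold after per-scaffold orientation
normalization.  Diagonal runs show collinearity, anti-diagonal runs show
inversions.  Images are derived views of that table; in stacked mode
each successive assembly is shifted up the y axis by a fixed offset
(default 5 Mb) so genomes do not overlap on the diagonal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .comparative import ScaffoldAssignment
from .io_formats import AlignmentRow
from .markers import parse_marker_id

__all__ = ["dotplot_points", "render"]

POINT_COLUMNS = [
    "assembly",
    "ref_chrom",
    "ref_start",
    "subject_id",
    "subject_pos",
    "strand",
    "y_offset",
]

_STRAND_COLOR = {"+": "#2c6fbb", "-": "#c0392b"}


def dotplot_points(
    kept_hits: Sequence[AlignmentRow],
    assignments: Sequence[ScaffoldAssignment],
    assembly_lengths: Mapping[str, int],
    label: str = "",
) -> pd.DataFrame:
    """Turn kept hits into dot-plot points (1-based coordinates).

    Every kept hit contributes one point; hits on minus-oriented
    scaffolds are mirrored into the scaffold's dominant orientation so a
    reverse-complemented but collinear scaffold still plots on y = x.
    """
    ori = {a.subject_id: a.orientation for a in assignments}
    rows = []
    for hit in kept_hits:
        chrom, ref_start = parse_marker_id(hit.query_id)
        if ori.get(hit.subject_id, "+") == "-":
            L = assembly_lengths[hit.subject_id]
            y0 = L - hit.subject_right
            strand = "-" if hit.strand == "+" else "+"
        else:
            y0 = hit.subject_left
            strand = hit.strand
        rows.append(
            {
                "assembly": label,
                "ref_chrom": chrom,
                "ref_start": ref_start + 1,
                "subject_id": hit.subject_id,
                "subject_pos": y0 + 1,
                "strand": strand,
                "y_offset": 0,
            }
        )
    return pd.DataFrame(rows, columns=POINT_COLUMNS)


def render(
    points: pd.DataFrame,
    out_png: str | Path,
    out_tsv: str | Path | None = None,
    stacked: bool = False,
    y_offset: int = 5_000_000,
    assembly_order: Sequence[str] | None = None,
    point_size: float = 4.0,
) -> Path:
    """Render one panel per chromosome; optionally stack assemblies.

    In stacked mode the i-th assembly's y values are shifted by
    ``i * y_offset``.  The exact points drawn (offset included) are
    written to ``out_tsv`` when given, so a plot can be reproduced from
    its table alone; rendering never drops or adds points.
    """
    points = points.copy()
    if assembly_order is None:
        assembly_order = list(dict.fromkeys(points["assembly"]))
    offsets = {
        label: (i * y_offset if stacked else 0) for i, label in enumerate(assembly_order)
    }
    points["y_offset"] = points["assembly"].map(offsets).fillna(0).astype(int)

    chroms = sorted(points["ref_chrom"].unique())
    ncols = min(4, max(1, len(chroms)))
    nrows = (len(chroms) + ncols - 1) // ncols if chroms else 1
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 3.2 * nrows), squeeze=False
    )
    for ax in axes.flat:
        ax.set_visible(False)
    for i, chrom in enumerate(chroms):
        ax = axes.flat[i]
        ax.set_visible(True)
        sub = points[points["ref_chrom"] == chrom]
        for strand, grp in sub.groupby("strand"):
            ax.scatter(
                grp["ref_start"],
                grp["subject_pos"] + grp["y_offset"],
                s=point_size,
                c=_STRAND_COLOR.get(strand, "#555555"),
                label=strand,
                linewidths=0,
            )
        ax.set_title(chrom, fontsize=9)
        ax.set_xlabel("reference position (bp)", fontsize=8)
        ax.set_ylabel("assembly position (bp)", fontsize=8)
        ax.tick_params(labelsize=7)
    fig.tight_layout()
    out_png = Path(out_png)
    fig.savefig(out_png, dpi=120)
    plt.close(fig)

    if out_tsv is not None:
        points.to_csv(out_tsv, sep="\t", index=False)
    return out_png
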