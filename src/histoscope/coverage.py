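"""Per-residue / per-PTM coverage matrices and heatmap rendering.

An identification set is condensed per protein into a (modification x
residue-position) grid of spectral counts plus a "backbone" row counting how
many PSMs span each residue.  The heatmap colours counts red->yellow scaled
relative to each protein (its own maximum maps to the top colour), so
densely sampled proteins do not drown sparse ones; absolute scaling is
available for cross-workflow comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap

from .io import IdentificationRecord, ProteinRecord
from .modifications import ModificationRegistry, default_registry

__all__ = [
    "CoverageMatrix",
    "build_coverage",
    "render_coverage_plot",
    "compare_coverage",
]

BACKBONE_ROW = "backbone"

#: red -> yellow, low -> high, on a dark background for zero.
_COVERAGE_CMAP = LinearSegmentedColormap.from_list(
    "coverage", ["#d7191c", "#fdae61", "#ffff66"]
)


@dataclass
class CoverageMatrix:
    """Spectral-count grid for one protein.

    ``rows`` lists the modification names; ``counts`` has shape
    ``(len(rows) + 1, length)`` with row 0 the backbone.
    """

    accession: str
    sequence: str
    rows: list[str]
    counts: np.ndarray

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def backbone(self) -> np.ndarray:
        return self.counts[0]

    def row(self, modification: str) -> np.ndarray:
        return self.counts[1 + self.rows.index(modification)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[BACKBONE_ROW, *self.rows],
            columns=range(1, self.length + 1),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="modification")


def build_coverage(
    records: Iterable[IdentificationRecord],
    protein: ProteinRecord,
    registry: ModificationRegistry | None = None,
    modification_rows: Sequence[str] | None = None,
) -> CoverageMatrix:
    """Condense identification records into a coverage matrix.

    The backbone row at position p counts the records whose [start, end]
    span contains p; each modification row counts records placing that
    modification at p.  Records for other accessions are skipped (reported
    via warning); placements naming modifications absent from the registry
    contribute to the backbone only.
    """
    registry = registry if registry is not None else default_registry()
    rows = list(modification_rows) if modification_rows is not None else registry.names
    counts = np.zeros((len(rows) + 1, len(protein)), dtype=int)
    row_index = {name: i + 1 for i, name in enumerate(rows)}

    n_skipped = 0
    unknown_mods: set[str] = set()
    for rec in records:
        if rec.accession != protein.accession:
            n_skipped += 1
            continue
        counts[0, rec.start - 1:rec.end] += 1
        for pep_pos, name in rec.modifications:
            if pep_pos == 0:
                continue  # N-terminal labels have no residue column
            if name not in row_index:
                unknown_mods.add(name)
                continue
            protein_pos = rec.start + pep_pos - 1
            counts[row_index[name], protein_pos - 1] += 1
    if n_skipped:
        warnings.warn(
            f"{n_skipped} record(s) for other accessions skipped while building "
            f"coverage of {protein.accession}"
        )
    if unknown_mods:
        warnings.warn(
            f"modification(s) {sorted(unknown_mods)} not in registry/rows; "
            "counted in backbone only"
        )
    return CoverageMatrix(protein.accession, protein.sequence, rows, counts)


def _draw_matrix(ax, matrix: CoverageMatrix, vmax: float | None,
                 show_markers: bool) -> None:
    data = matrix.counts.astype(float)
    if vmax is None:
        # relative scaling: colour encodes the fraction of this protein's
        # maximum count, so a global rescaling of counts changes nothing
        data = data / (data.max() or 1.0)
        top = 1.0
    else:
        top = vmax
    masked = np.ma.masked_equal(data, 0.0)
    cmap = _COVERAGE_CMAP.copy()
    cmap.set_bad("#202040")
    im = ax.imshow(masked, aspect="auto", interpolation="nearest",
                   cmap=cmap, vmin=0.0, vmax=top)
    ax.set_yticks(range(len(matrix.rows) + 1))
    ax.set_yticklabels([BACKBONE_ROW, *matrix.rows], fontsize=6)
    if matrix.length <= 120:
        ax.set_xticks(range(matrix.length))
        ax.set_xticklabels(list(matrix.sequence), fontsize=4)
    elif show_markers:
        ticks = list(range(9, matrix.length, 10))
        ax.set_xticks(ticks)
        ax.set_xticklabels([str(t + 1) for t in ticks], fontsize=5)
    else:
        ax.set_xticks([])
    plt.colorbar(im, ax=ax, fraction=0.03, pad=0.01)


def render_coverage_plot(
    matrix: CoverageMatrix,
    path: str | Path,
    show_markers: bool = False,
    relative_scaling: bool = True,
    vmax: float | None = None,
    title: str | None = None,
) -> None:
    """Render one coverage matrix as a red->yellow heatmap.

    With ``relative_scaling`` (default) the protein's own maximum count maps
    to the top colour, so the image is invariant to a global rescaling of
    counts; pass ``vmax`` with ``relative_scaling=False`` to pin an absolute
    scale.  ``show_markers`` adds position ticks every 10 residues.
    """
    if matrix.length == 0:
        raise ValueError("cannot render a zero-length coverage matrix")
    fig, ax = plt.subplots(
        figsize=(max(6.0, matrix.length / 18), 0.9 + 0.22 * (len(matrix.rows) + 1))
    )
    _draw_matrix(ax, matrix, None if relative_scaling else vmax, show_markers)
    ax.set_title(title or matrix.accession, fontsize=9)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def compare_coverage(
    matrices: Mapping[str, CoverageMatrix],
    path: str | Path | None = None,
    regions: Sequence[tuple[int, int]] | None = None,
    show_markers: bool = False,
) -> pd.DataFrame:
    """Stack per-workflow coverage of one protein and tabulate region sums.

    All matrices must describe the same protein.  Returns a DataFrame of
    backbone-count sums per user-defined region (1-based inclusive spans;
    default: the whole protein) per workflow; optionally writes a stacked
    multi-panel heatmap aligned on the shared backbone.
    """
    if not matrices:
        raise ValueError("no coverage matrices given")
    first = next(iter(matrices.values()))
    for m in matrices.values():
        if m.accession != first.accession or m.length != first.length:
            raise ValueError("compare_coverage requires matrices of one protein")
    if regions is None:
        regions = [(1, first.length)]

    table = pd.DataFrame(
        {
            workflow: [int(m.backbone[a - 1:b].sum()) for a, b in regions]
            for workflow, m in matrices.items()
        },
        index=[f"{a}-{b}" for a, b in regions],
    )
    table.index.name = "region"

    if path is not None:
        n = len(matrices)
        fig, axes = plt.subplots(
            n, 1, squeeze=False, sharex=True,
            figsize=(max(6.0, first.length / 18),
                     n * (0.9 + 0.22 * (len(first.rows) + 1))),
        )
        for ax, (workflow, m) in zip(axes.ravel(), matrices.items()):
            _draw_matrix(ax, m, None, show_markers)
            ax.set_title(f"{m.accession} — {workflow}", fontsize=9)
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return table
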