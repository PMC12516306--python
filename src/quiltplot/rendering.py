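"""Triangular-matrix layout and figure rendering.

The n sequences span an n x n grid; cell (i, j) with i <= j shows the
dot plot of sequences i (row) and j (column), placed at (row i, col j)
in upper mode and at its transpose in lower mode.  Diagonal cells hold
self-alignments.  Cell widths and heights are proportional to sequence
lengths so one bp-per-inch scale holds across the whole figure.

Axis convention: the column sequence is on x and the row sequence on y.
For the ordered pair (i, j), sequence i is the alignment target, so in
lower mode x carries the target and a '+' alignment runs from
(t_start, q_start) to (t_end, q_end); upper mode is the transpose.  The
slope sign always equals the strand sign.

Geometry is produced as plain primitive lists (segments, guide lines,
rectangles) so tests can assert on them without a graphics backend;
`render_matrix` draws the primitives to PNG (raster, >=300 dpi) and PDF
(vector, creation timestamp suppressed for byte-stable reruns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.collections import LineCollection
from matplotlib.colors import to_rgba
from matplotlib.figure import Figure

from .alignment_io import AlignmentRecord, sanitize_id
from .config_io import AnnotationInterval, SequenceEntry
from .errors import ContractError, InputValidationError
from .styling import RenderStyle, StyledSegment, color_for_pi

log = logging.getLogger("quiltplot.render")

RGBA = tuple[float, float, float, float]
Rect = tuple[float, float, float, float]  # (x0, y0, w, h), normalized figure coords

#: bp rendered per inch of figure by default; total data extent is clamped
#: to a readable range and the style's overrides may rescale it.
DEFAULT_BP_PER_INCH = 50_000.0
MIN_DATA_IN, MAX_DATA_IN = 3.0, 30.0
CELL_GAP_IN = 0.08
LABEL_MARGIN_IN = 0.8
EDGE_MARGIN_IN = 0.3
ANNOT_STRIP_IN = 0.18
ANNOT_PAD_IN = 0.06
LEGEND_HEIGHT_IN = 0.9
PNG_DPI = 300


@dataclass
class MatrixLayout:
    """Cell geometry of the triangular plot in normalized figure coordinates."""

    n: int
    side: str  # 'upper' | 'lower'
    axis_extent: list[tuple[float, float]]  # per sequence, (0, length)
    cell_boxes: dict[tuple[int, int], Rect]
    annot_boxes: dict[int, Rect] = field(default_factory=dict)
    legend_box: Rect | None = None
    fig_size: tuple[float, float] = (6.0, 6.0)  # inches


@dataclass(frozen=True)
class Segment:
    """One alignment drawn in one cell, endpoints in cell data coordinates."""

    cell: tuple[int, int]
    p0: tuple[float, float]
    p1: tuple[float, float]
    color: RGBA
    width: float


@dataclass(frozen=True)
class LinePrimitive:
    """A breakpoint guide line spanning a full cell axis.

    ``axis`` 'x' is a vertical line at x=coord; 'y' a horizontal line at
    y=coord.
    """

    cell: tuple[int, int]
    axis: str
    coord: float
    color: str
    width: float


@dataclass(frozen=True)
class RectPrimitive:
    """One annotation rectangle spanning [start, end) bp on its track."""

    start: float
    end: float
    color: RGBA


@dataclass(frozen=True)
class LegendSpec:
    """Percent-identity legend: a color bar, or a single swatch."""

    kind: str  # 'colorbar' | 'swatch'
    min_pi: float
    max_pi: float
    colors: tuple[RGBA, ...]  # sampled in ascending-PI order (colorbar mode)


def build_layout(
    entries: list[SequenceEntry],
    side: str = "upper",
    show_annot: bool = False,
    with_legend: bool = True,
    bp_per_inch: float = DEFAULT_BP_PER_INCH,
) -> MatrixLayout:
    """Place the n(n+1)/2 cells, annotation strips and legend on the figure.

    Cell sizes are proportional to sequence lengths; annotation strips sit
    on the outer margin adjacent to each sequence's axis (top for upper
    mode, left for lower).
    """
    n = len(entries)
    if n == 0:
        raise InputValidationError("layout needs at least one sequence")
    if side not in ("upper", "lower"):
        raise InputValidationError(f"side must be 'upper' or 'lower', got {side!r}")
    lengths = [float(e.length) for e in entries]
    if any(L <= 0 for L in lengths):
        raise InputValidationError("all sequence lengths must be known and positive")

    total_bp = sum(lengths)
    data_in = total_bp / bp_per_inch
    scale = bp_per_inch
    if data_in < MIN_DATA_IN:
        scale = total_bp / MIN_DATA_IN
    elif data_in > MAX_DATA_IN:
        scale = total_bp / MAX_DATA_IN
    sizes = [L / scale for L in lengths]  # per-sequence extent, inches

    left = LABEL_MARGIN_IN if side == "lower" else EDGE_MARGIN_IN
    top = LABEL_MARGIN_IN if side == "upper" else EDGE_MARGIN_IN
    right = EDGE_MARGIN_IN
    bottom = EDGE_MARGIN_IN
    strip = ANNOT_STRIP_IN + ANNOT_PAD_IN if show_annot else 0.0
    if side == "upper":
        top += strip
    else:
        left += strip
    legend_h = LEGEND_HEIGHT_IN if with_legend else 0.0
    bottom += legend_h

    span = sum(sizes) + (n - 1) * CELL_GAP_IN
    fig_w = left + span + right
    fig_h = top + span + bottom

    # column x offsets (from left) and row y offsets (top edge from figure top)
    col_x = []
    x = left
    for s in sizes:
        col_x.append(x)
        x += s + CELL_GAP_IN
    row_top = []
    y = top
    for s in sizes:
        row_top.append(y)
        y += s + CELL_GAP_IN

    def norm(x0: float, y0: float, w: float, h: float) -> Rect:
        return (x0 / fig_w, y0 / fig_h, w / fig_w, h / fig_h)

    cell_boxes: dict[tuple[int, int], Rect] = {}
    for i in range(n):
        for j in range(i, n):
            row, col = (i, j) if side == "upper" else (j, i)
            x0 = col_x[col]
            y0 = fig_h - row_top[row] - sizes[row]
            cell_boxes[(i, j)] = norm(x0, y0, sizes[col], sizes[row])

    annot_boxes: dict[int, Rect] = {}
    if show_annot:
        for k in range(n):
            if side == "upper":
                y0 = fig_h - top + ANNOT_PAD_IN
                annot_boxes[k] = norm(col_x[k], y0, sizes[k], ANNOT_STRIP_IN)
            else:
                x0 = left - strip
                y0 = fig_h - row_top[k] - sizes[k]
                annot_boxes[k] = norm(x0, y0, ANNOT_STRIP_IN, sizes[k])

    legend_box = None
    if with_legend:
        lw = min(4.0, 0.6 * fig_w)
        legend_box = norm((fig_w - lw) / 2.0, 0.45, lw, 0.22)

    return MatrixLayout(
        n=n,
        side=side,
        axis_extent=[(0.0, L) for L in lengths],
        cell_boxes=cell_boxes,
        annot_boxes=annot_boxes,
        legend_box=legend_box,
        fig_size=(fig_w, fig_h),
    )


def segments_for_cell(
    styled: list[StyledSegment],
    cell: tuple[int, int],
    side: str = "upper",
    lwidth: float = 1.0,
    target_len: float | None = None,
    query_len: float | None = None,
) -> list[Segment]:
    """Turn styled alignment records into drawable segments for one cell.

    A '+' alignment runs corner-to-corner with positive slope, a '-' one
    with negative slope; upper mode puts the query on x, lower the target.
    """
    x_is_target = side == "lower"
    out: list[Segment] = []
    for ss in styled:
        rec = ss.record
        if target_len is not None and rec.t_end > target_len:
            raise ContractError(
                f"record target end {rec.t_end} exceeds axis extent {target_len}"
            )
        if query_len is not None and rec.q_end > query_len:
            raise ContractError(
                f"record query end {rec.q_end} exceeds axis extent {query_len}"
            )
        if rec.strand == "+":
            t_pts = (rec.t_start, rec.t_end)
            q_pts = (rec.q_start, rec.q_end)
        else:
            t_pts = (rec.t_start, rec.t_end)
            q_pts = (rec.q_end, rec.q_start)
        if x_is_target:
            p0, p1 = (t_pts[0], q_pts[0]), (t_pts[1], q_pts[1])
        else:
            p0, p1 = (q_pts[0], t_pts[0]), (q_pts[1], t_pts[1])
        out.append(Segment(cell=cell, p0=p0, p1=p1, color=ss.color, width=lwidth))
    return out


def breakpoint_lines(
    records: list[AlignmentRecord],
    cell: tuple[int, int],
    side: str = "upper",
    color: str = "#7F7F7F",
    width: float = 0.2,
) -> list[LinePrimitive]:
    """Guide lines at every alignment start/end, deduplicated per (axis, coord).

    Each record contributes two lines on the target axis and two on the
    query axis, spanning the full opposite extent of its own cell.
    """
    t_axis = "x" if side == "lower" else "y"
    q_axis = "y" if side == "lower" else "x"
    seen: set[tuple[str, float]] = set()
    out: list[LinePrimitive] = []
    for rec in records:
        for axis, coord in (
            (t_axis, rec.t_start), (t_axis, rec.t_end),
            (q_axis, rec.q_start), (q_axis, rec.q_end),
        ):
            key = (axis, float(coord))
            if key in seen:
                continue
            seen.add(key)
            out.append(LinePrimitive(cell=cell, axis=axis, coord=float(coord),
                                     color=color, width=width))
    return out


def annotation_track(
    intervals: list[AnnotationInterval], entry: SequenceEntry
) -> list[RectPrimitive]:
    """Filled rectangles for one sequence's annotation strip (black by default)."""
    out: list[RectPrimitive] = []
    for iv in intervals:
        if iv.end > entry.length:
            raise ContractError(
                f"annotation [{iv.start}, {iv.end}) exceeds length {entry.length} "
                f"of {entry.sample_id!r}"
            )
        if iv.color is not None:
            color = (iv.color[0] / 255.0, iv.color[1] / 255.0, iv.color[2] / 255.0, 1.0)
        else:
            color = (0.0, 0.0, 0.0, 1.0)
        out.append(RectPrimitive(start=float(iv.start), end=float(iv.end), color=color))
    return out


def render_legend(style: RenderStyle, samples: int = 64) -> LegendSpec:
    """Legend primitives consistent with `style_records` color resolution."""
    if style.single_color is not None:
        return LegendSpec(kind="swatch", min_pi=style.min_pi, max_pi=style.max_pi,
                          colors=(to_rgba(style.single_color),))
    pis = np.linspace(style.min_pi, style.max_pi, samples)
    colors = tuple(color_for_pi(float(pi), style) for pi in pis)
    return LegendSpec(kind="colorbar", min_pi=style.min_pi, max_pi=style.max_pi,
                      colors=colors)


def _draw_cell(fig: Figure, box: Rect, xlim, ylim,
               segments: list[Segment], lines: list[LinePrimitive]) -> None:
    ax = fig.add_axes(box)
    ax.set_xlim(*xlim)
    ax.set_ylim(*ylim)
    ax.set_xticks([])
    ax.set_yticks([])
    for sp in ax.spines.values():
        sp.set_linewidth(0.5)
    # breakpoint guides beneath the alignment segments
    for ln in lines:
        if ln.axis == "x":
            ax.axvline(ln.coord, color=ln.color, linewidth=ln.width, zorder=1)
        else:
            ax.axhline(ln.coord, color=ln.color, linewidth=ln.width, zorder=1)
    if segments:
        coll = LineCollection(
            [(s.p0, s.p1) for s in segments],
            colors=[s.color for s in segments],
            linewidths=[s.width for s in segments],
            zorder=2,
        )
        ax.add_collection(coll)


def _draw_track(fig: Figure, box: Rect, extent, rects: list[RectPrimitive],
                horizontal: bool) -> None:
    ax = fig.add_axes(box)
    ax.set_xticks([])
    ax.set_yticks([])
    for sp in ax.spines.values():
        sp.set_linewidth(0.4)
    if horizontal:
        ax.set_xlim(*extent)
        ax.set_ylim(0, 1)
        for r in rects:
            ax.axvspan(r.start, r.end, color=r.color, linewidth=0)
    else:
        ax.set_ylim(*extent)
        ax.set_xlim(0, 1)
        for r in rects:
            ax.axhspan(r.start, r.end, color=r.color, linewidth=0)


def _draw_legend(fig: Figure, box: Rect, spec: LegendSpec) -> None:
    ax = fig.add_axes(box)
    if spec.kind == "swatch":
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.axvspan(0.0, 0.12, color=spec.colors[0], linewidth=0)
        ax.text(0.16, 0.5, "alignment", va="center", fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
        for sp in ax.spines.values():
            sp.set_visible(False)
        return
    arr = np.array([spec.colors])
    ax.imshow(arr, aspect="auto", extent=(spec.min_pi, spec.max_pi, 0, 1),
              interpolation="nearest", origin="lower")
    ax.set_yticks([])
    ax.set_xticks([spec.min_pi, spec.max_pi])
    ax.tick_params(labelsize=7, length=2)
    ax.set_xlabel("percent identity", fontsize=8)


def _savefig(fig: Figure, prefix: Path, transparent: bool) -> list[Path]:
    png = prefix.with_suffix(".png")
    pdf = prefix.with_suffix(".pdf")
    fig.savefig(png, dpi=PNG_DPI, transparent=transparent)
    # a fixed CreationDate keeps the vector output byte-stable across reruns
    fig.savefig(pdf, metadata={"CreationDate": None})
    return [png, pdf]


def render_matrix(
    layout: MatrixLayout,
    entries: list[SequenceEntry],
    cell_segments: dict[tuple[int, int], list[Segment]],
    cell_lines: dict[tuple[int, int], list[LinePrimitive]],
    tracks: dict[int, list[RectPrimitive]],
    out_dir: str | Path,
    style: RenderStyle,
    labels: list[str] | None = None,
) -> list[Path]:
    """Draw the combined matrix and all individual pairwise plots.

    Writes ``<out_dir>/quiltplot.{png,pdf}`` plus
    ``<out_dir>/pairwise/<idA>__<idB>.{png,pdf}`` and returns all paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = labels if labels is not None else [e.label for e in entries]
    extents = layout.axis_extent
    written: list[Path] = []

    fig = Figure(figsize=layout.fig_size)
    for (i, j), box in sorted(layout.cell_boxes.items()):
        row, col = ((i, j) if layout.side == "upper" else (j, i))
        _draw_cell(fig, box, extents[col], extents[row],
                   cell_segments.get((i, j), []), cell_lines.get((i, j), []))
    if style.show_annot:
        for k, box in layout.annot_boxes.items():
            _draw_track(fig, box, extents[k], tracks.get(k, []),
                        horizontal=(layout.side == "upper"))
    # one label per sequence on the margin adjacent to its strip/axis
    for k in range(layout.n):
        key = (0, k) if layout.side == "upper" else (k, k)
        box = layout.cell_boxes[(min(key), max(key))]
        if layout.side == "upper":
            fig.text(box[0] + box[2] / 2.0, 1.0 - 0.25 / layout.fig_size[1],
                     labels[k], ha="center", va="top", fontsize=9)
        else:
            diag = layout.cell_boxes[(k, k)]
            fig.text(0.02, diag[1] + diag[3] / 2.0, labels[k],
                     ha="left", va="center", fontsize=9, rotation=90)
    if layout.legend_box is not None:
        _draw_legend(fig, layout.legend_box, render_legend(style))
    written += _savefig(fig, out_dir / "quiltplot", style.transparent)

    pair_dir = out_dir / "pairwise"
    pair_dir.mkdir(exist_ok=True)
    for (i, j) in sorted(layout.cell_boxes):
        row, col = ((i, j) if layout.side == "upper" else (j, i))
        w_bp = extents[col][1]
        h_bp = extents[row][1]
        aspect = h_bp / w_bp
        pw = 4.0
        pfig = Figure(figsize=(pw + 1.0, pw * aspect + 1.0))
        box = (0.12, 0.12 / max(aspect, 0.4), 0.8, 0.8)
        _draw_cell(pfig, box, extents[col], extents[row],
                   cell_segments.get((i, j), []), cell_lines.get((i, j), []))
        ax = pfig.axes[0]
        ax.set_xlabel(labels[col], fontsize=9)
        ax.set_ylabel(labels[row], fontsize=9)
        name = f"{sanitize_id(entries[i].sample_id)}__{sanitize_id(entries[j].sample_id)}"
        written += _savefig(pfig, pair_dir / name, style.transparent)
    log.info("wrote %d files under %s", len(written), out_dir)
    return written
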