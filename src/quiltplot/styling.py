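"""Length filtering and percent-identity color mapping.

Percent identity (PI) is clamped to the user range [min_pi, max_pi]
(defaults 85 and 100), mapped affinely onto [0, 1] and projected into a
matplotlib colormap (default "rainbow", reversed by default).  Values
outside the range take the closest boundary.  Alignment "length" for
both the display and the breakpoint threshold is max(l1, l2), the longer
of the two aligned spans — symmetric in the pair and conservative toward
showing structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
from matplotlib.colors import to_rgba

from .alignment_io import AlignmentRecord
from .errors import ConfigurationError

RGBA = tuple[float, float, float, float]


@dataclass
class RenderStyle:
    """All visualization parameters with their documented defaults."""

    min_len: int = 5000  # bp; minimum alignment span to display
    min_pi: float = 85.0  # percent identity mapped to colormap position 0
    max_pi: float = 100.0  # percent identity mapped to colormap position 1
    cmap: str = "rainbow"
    single_color: str | None = None  # overrides cmap when set
    reverse_cmap: bool = True
    lwidth: float = 1.0
    transparent: bool = False
    show_annot: bool = False
    show_bp: bool = False
    bp_color: str = "#7F7F7F"
    bp_lwidth: float = 0.2
    bp_min_len: int = 10000  # bp; minimum span for breakpoint lines
    matrix_side: str = "upper"  # 'upper' | 'lower'

    def __post_init__(self) -> None:
        if self.min_pi >= self.max_pi:
            raise ConfigurationError(
                f"min_pi ({self.min_pi}) must be smaller than max_pi ({self.max_pi})"
            )
        if self.min_len < 0 or self.bp_min_len < 0:
            raise ConfigurationError("length thresholds must be non-negative")
        if self.lwidth <= 0 or self.bp_lwidth <= 0:
            raise ConfigurationError("line widths must be positive")
        if self.matrix_side not in ("upper", "lower"):
            raise ConfigurationError(f"matrix_side must be 'upper' or 'lower'")


@dataclass(frozen=True)
class StyledSegment:
    """An alignment record with its resolved display color."""

    record: AlignmentRecord
    color: RGBA
    unit_value: float  # clamped, normalized PI in [0, 1]


def filter_by_length(records: list[AlignmentRecord], min_len: int) -> list[AlignmentRecord]:
    """Keep records whose span max(l1, l2) is at least ``min_len`` (order kept)."""
    if min_len < 0:
        raise ConfigurationError("min_len must be non-negative")
    return [r for r in records if r.span >= min_len]


def select_breakpoint_records(
    records: list[AlignmentRecord], bp_min_len: int
) -> list[AlignmentRecord]:
    """Records long enough to contribute breakpoint lines (independent threshold)."""
    return filter_by_length(records, bp_min_len)


def pi_to_unit(pi: float, min_pi: float, max_pi: float) -> float:
    """Clamp ``pi`` into [min_pi, max_pi] and rescale affinely onto [0, 1]."""
    if min_pi >= max_pi:
        raise ConfigurationError(f"min_pi ({min_pi}) must be smaller than max_pi ({max_pi})")
    clamped = min(max(pi, min_pi), max_pi)
    return (clamped - min_pi) / (max_pi - min_pi)


def _colormap(name: str):
    try:
        return matplotlib.colormaps[name]
    except KeyError:
        raise ConfigurationError(f"unknown colormap {name!r}") from None


def color_for_pi(pi: float, style: RenderStyle) -> RGBA:
    """Resolve the display color of one PI value under a style."""
    u = pi_to_unit(pi, style.min_pi, style.max_pi)
    if style.single_color is not None:
        try:
            return to_rgba(style.single_color)
        except ValueError:
            raise ConfigurationError(f"unknown color {style.single_color!r}") from None
    cmap = _colormap(style.cmap)
    return tuple(cmap(1.0 - u if style.reverse_cmap else u))


def style_records(records: list[AlignmentRecord], style: RenderStyle) -> list[StyledSegment]:
    """Attach colors to records; unit values are computed even in single-color
    mode so the legend can still report the PI range."""
    out = []
    for rec in records:
        u = pi_to_unit(rec.percent_identity, style.min_pi, style.max_pi)
        out.append(StyledSegment(record=rec, color=color_for_pi(rec.percent_identity, style),
                                 unit_value=u))
    return out
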