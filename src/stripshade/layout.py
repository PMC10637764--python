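"""Strip-intercropping field geometry.

A layout is a repeating pattern of maize strips and soybean strips (e.g.
2M3S = 2 maize rows + 3 soybean rows). Soybean rows are indexed R1..Rn from
south to north. For shading, the origin is the midpoint between the soybean
strip and the adjacent maize strip that casts the shadow, so each row has two
origin distances D_mr: one for the northern source strip and one for the
southern source strip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["StripLayout", "RowGeometry", "row_distances"]


@dataclass(frozen=True)
class StripLayout:
    """Planting configuration of one maize/soybean strip pattern.

    Parameters
    ----------
    configuration:
        Label such as ``"2M3S"`` or ``"3M6S"``.
    n_maize_rows, n_soybean_rows:
        Rows per maize strip and per soybean strip.
    row_spacing:
        D_r, spacing between adjacent rows within a strip (m).
    strip_distance:
        D_ms, row distance between adjacent maize and soybean strips (m).
    planting_direction:
        gamma (degrees), counterclockwise from north; 0 = rows run north-south.
        Stored axially in [0, 180).
    latitude:
        Site latitude (degrees north).
    row_widths:
        Optional per-row widths w_i (m) for strip aggregation; defaults to
        D_r for every row, making the strip value the plain row mean.
    """

    configuration: str = "2M3S"
    n_maize_rows: int = 2
    n_soybean_rows: int = 3
    row_spacing: float = 0.6
    strip_distance: float = 0.6
    planting_direction: float = 59.0
    latitude: float = 43.267
    row_widths: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_maize_rows < 1 or self.n_soybean_rows < 1:
            raise ValueError("strip must contain at least one row of each crop")
        if self.row_spacing <= 0 or self.strip_distance <= 0:
            raise ValueError("row spacing and strip distance must be positive")
        if not 0.0 <= self.planting_direction < 180.0:
            object.__setattr__(self, "planting_direction", self.planting_direction % 180.0)
        if self.row_widths is not None and len(self.row_widths) != self.n_soybean_rows:
            raise ValueError("row_widths must have one entry per soybean row")

    @property
    def widths(self) -> tuple[float, ...]:
        if self.row_widths is not None:
            return self.row_widths
        return (self.row_spacing,) * self.n_soybean_rows


@dataclass(frozen=True)
class RowGeometry:
    """One soybean row's origin distances (R1 = southernmost)."""

    row_index: int  # 1-based from the south
    d_mr_south_source: float  # distance to the southern-strip origin (m)
    d_mr_north_source: float  # distance to the northern-strip origin (m)
    width: float  # w_i (m)


def row_distances(layout: StripLayout) -> list[RowGeometry]:
    """Origin distances D_mr for every soybean row of a strip.

    The origin sits midway between the soybean strip and the shading maize
    strip, i.e. D_ms / 2 beyond the nearest soybean row, so row i (from the
    south) is at ``D_ms/2 + (i-1) D_r`` from the southern source and
    ``D_ms/2 + (n-i) D_r`` from the northern source.
    """
    n = layout.n_soybean_rows
    half = layout.strip_distance / 2.0
    widths = layout.widths
    return [
        RowGeometry(
            row_index=i,
            d_mr_south_source=half + (i - 1) * layout.row_spacing,
            d_mr_north_source=half + (n - i) * layout.row_spacing,
            width=widths[i - 1],
        )
        for i in range(1, n + 1)
    ]
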