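"""Input-sensitivity sweeps for the shading capacity model.

Each sweep varies one input — the canopy-height difference H_ms, the planting
direction gamma, or the site latitude — over a grid while holding the others
fixed, and reports the mean daily strip shading proportion (SP_strip) over a
growth period. Crop growth is assumed identical at every grid point (the same
H_ms series is reused), so the sweeps isolate the geometric effect of the
varied input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import StripLayout, row_distances
from .shading import _day_grid, _mask_to_intervals, _shaded_mask, aggregate_strip, shading_proportion
from .solar import PolarDayNightError, day_context

__all__ = ["SweepSpec", "sweep"]

VARIABLES = ("height_difference", "direction", "latitude")


@dataclass(frozen=True)
class SweepSpec:
    """One-variable sweep definition.

    ``h_ms`` is a DataFrame indexed by date with columns ``north``/``south``;
    for the height-difference sweep its dates define the period and the grid
    value replaces both sides with a constant.
    """

    variable: str
    values: tuple[float, ...]
    layout: StripLayout = field(default_factory=StripLayout)
    h_ms: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"variable must be one of {VARIABLES}, got {self.variable!r}")
        if len(self.values) == 0:
            raise ValueError("sweep grid is empty")
        if self.h_ms is None or len(self.h_ms) == 0:
            raise ValueError("a daily H_ms frame is required (it defines the period)")
        if self.variable == "direction" and not all(0 <= v <= 180 for v in self.values):
            raise ValueError("direction grid must lie in [0, 180] degrees")


def _mean_sp_strip(
    layout: StripLayout,
    h_ms: pd.DataFrame,
    step_minutes: float,
) -> float:
    """Mean daily SP_strip over the period (unweighted across days)."""
    rows = row_distances(layout)
    widths = layout.widths
    daily = []
    for d in h_ms.index:
        doy = pd.Timestamp(d).dayofyear
        ctx = day_context(doy, layout.latitude)
        edges, alpha, beta = _day_grid(ctx, step_minutes)
        hn = float(h_ms.loc[d, "north"])
        hs = float(h_ms.loc[d, "south"])
        sps = []
        for row in rows:
            shaded, north_source = _shaded_mask(
                alpha, beta, layout.planting_direction, hn, hs,
                row.d_mr_north_source, row.d_mr_south_source,
            )
            ivs = _mask_to_intervals(shaded, north_source, edges)
            sps.append(shading_proportion(ivs, ctx))
        daily.append(aggregate_strip(sps, widths))
    return float(np.mean(daily))


def sweep(spec: SweepSpec, step_minutes: float = 1.0) -> pd.DataFrame:
    """Run a sweep; returns a tidy frame ``variable, value, SP_strip, flagged``.

    Grid points where the sun never rises or never sets on some period day
    (possible only at extreme latitudes) are flagged with ``SP_strip = NaN``
    rather than dropped.
    """
    records = []
    for v in spec.values:
        layout = spec.layout
        h_ms = spec.h_ms
        if spec.variable == "height_difference":
            if v < 0:
                raise ValueError("height difference must be >= 0")
            h_ms = pd.DataFrame({"north": v, "south": v}, index=spec.h_ms.index, dtype=float)
        elif spec.variable == "direction":
            layout = replace(layout, planting_direction=float(v) % 180.0)
        else:
            layout = replace(layout, latitude=float(v))
        try:
            sp = _mean_sp_strip(layout, h_ms, step_minutes)
            flagged = False
        except PolarDayNightError:
            sp, flagged = np.nan, True
        records.append(
            {"variable": spec.variable, "value": float(v), "SP_strip": sp, "flagged": flagged}
        )
    return pd.DataFrame(records)
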