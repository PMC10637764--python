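"""Shading capacity model (SCM) for maize shading on soybean rows.

The model treats each maize strip as an opaque cuboid taller than the soybean
canopy by H_ms (the canopy-height difference, kept separate for the strip
north and south of the soybean strip). At any instant with sun elevation
alpha and azimuth beta, the shadow reaches a signed cross-row distance

    D_s = H_ms / tan(alpha) * cos(beta + gamma - 90 deg)

where gamma is the planting direction (counterclockwise from north). Positive
D_s means the shadow falls southward, i.e. the soybean strip is shaded by its
*northern* maize strip; negative D_s means shading from the southern strip. A
row at origin distance D_mr (for the active source side) is shaded at that
instant iff |D_s| > D_mr.

Scanning a day at a fixed time step yields per-row shaded intervals. The
shading proportion SP weights those intervals by the sinusoidal daily
radiation-intensity proxy I_s = sin(alpha): SP is the integral of sin(alpha)
d(alpha) over the shaded elevation branches divided by the same integral over
the whole day, which reduces to cosine differences of the boundary
elevations. Daily shading capacity is SC = R_a * SP (MJ m^-2) with R_a the
day's direct radiation, and CSC accumulates SC over a period. Strip-level SP
and SC are row-width-weighted means. Diffuse-light shading and transmission
through the maize canopy are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd

from .layout import RowGeometry, StripLayout, row_distances
from .solar import DayContext, day_context

logger = logging.getLogger(__name__)

__all__ = [
    "ShadingInterval",
    "DailyShadingResult",
    "CSCTable",
    "shading_distance",
    "daily_intervals",
    "shading_proportion",
    "shading_capacity",
    "aggregate_strip",
    "simulate_day",
    "simulate_period",
    "cumulate",
]


@dataclass(frozen=True)
class ShadingInterval:
    """One contiguous shaded spell for a row (LST hours)."""

    start: float
    end: float
    source: str  # "north" or "south" (which maize strip casts the shadow)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"interval end {self.end} must exceed start {self.start}")
        if self.source not in ("north", "south"):
            raise ValueError(f"source must be 'north' or 'south', got {self.source!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class DailyShadingResult:
    """Per-row daily shading summary."""

    row_index: int
    date: Date
    intervals: tuple[ShadingInterval, ...]
    shading_time: float  # hours
    sp: float  # shading proportion, 0..1
    sc: float  # shading capacity, MJ m^-2


@dataclass
class CSCTable:
    """Season-level shading bookkeeping for one strip layout."""

    rows: pd.DataFrame  # columns: date, row, shading_time_h, SP, SC
    strip: pd.DataFrame  # columns: date, SP_strip, SC_strip
    csc_per_row: pd.Series  # index: row, values: MJ m^-2
    overall_csc: float  # MJ m^-2

    def __post_init__(self) -> None:
        self.rows = self.rows.reset_index(drop=True)
        self.strip = self.strip.reset_index(drop=True)


def shading_distance(
    h_ms: float,
    elevation_deg: float | np.ndarray,
    azimuth_deg: float | np.ndarray,
    direction_deg: float,
) -> float | np.ndarray:
    """Signed cross-row shadow reach D_s (m); NaN where the sun is down."""
    if h_ms < 0:
        raise ValueError(f"H_ms must be >= 0, got {h_ms}")
    a = np.asarray(elevation_deg, dtype=float)
    b = np.asarray(azimuth_deg, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ds = h_ms / np.tan(np.deg2rad(a)) * np.cos(np.deg2rad(b + direction_deg - 90.0))
    ds = np.where(a > 0, ds, np.nan)
    return float(ds) if np.isscalar(elevation_deg) else ds


def _day_grid(ctx: DayContext, step_minutes: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step edges and midpoint solar angles from sunrise to sunset."""
    if step_minutes <= 0:
        raise ValueError("step_minutes must be positive")
    dt = step_minutes / 60.0
    n = int(np.ceil((ctx.sunset_lst - ctx.sunrise_lst) / dt))
    edges = ctx.sunrise_lst + dt * np.arange(n + 1)
    edges[-1] = ctx.sunset_lst  # last step may be partial
    mids = 0.5 * (edges[:-1] + edges[1:])
    alpha = np.asarray(ctx.elevation_at(mids))
    beta = np.asarray(ctx.azimuth_at(mids))
    return edges, alpha, beta


def _mask_to_intervals(
    shaded: np.ndarray, north_source: np.ndarray, edges: np.ndarray
) -> list[ShadingInterval]:
    """Merge contiguous shaded steps (same source) into intervals."""
    # 0 = unshaded, 1 = shaded from the south strip, 2 = from the north strip
    state = np.where(shaded, np.where(north_source, 2, 1), 0)
    bounds = np.r_[0, np.flatnonzero(np.diff(state)) + 1, state.size]
    out: list[ShadingInterval] = []
    for i, j in zip(bounds[:-1], bounds[1:]):
        if state[i] == 0:
            continue
        out.append(
            ShadingInterval(
                start=float(edges[i]),
                end=float(edges[j]),
                source="north" if state[i] == 2 else "south",
            )
        )
    return out


def daily_intervals(
    ctx: DayContext,
    row: RowGeometry,
    layout: StripLayout,
    h_ms_north: float,
    h_ms_south: float,
    step_minutes: float = 1.0,
) -> list[ShadingInterval]:
    """Shaded intervals for one row on one day, by time-step scan.

    At each step the shadow direction picks the source strip: a southward
    shadow (positive D_s) comes from the northern strip and is tested with
    that side's H_ms and D_mr, and vice versa.
    """
    edges, alpha, beta = _day_grid(ctx, step_minutes)
    shaded, north_source = _shaded_mask(
        alpha, beta, layout.planting_direction, h_ms_north, h_ms_south,
        row.d_mr_north_source, row.d_mr_south_source,
    )
    return _mask_to_intervals(shaded, north_source, edges)


def _shaded_mask(
    alpha: np.ndarray,
    beta: np.ndarray,
    direction_deg: float,
    h_north: float,
    h_south: float,
    d_mr_north: float,
    d_mr_south: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised shaded test over a day's solar-angle arrays.

    The sign of cos(beta + gamma - 90) alone decides the source side (tan
    alpha and H_ms are both positive), so the geometric factor is computed
    once and scaled by the side-specific H_ms.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        geom = np.cos(np.deg2rad(beta + direction_deg - 90.0)) / np.tan(np.deg2rad(alpha))
    geom = np.where(alpha > 0, geom, 0.0)
    north_source = geom > 0
    ds = np.where(north_source, h_north * geom, h_south * geom)
    d_mr = np.where(north_source, d_mr_north, d_mr_south)
    return np.abs(ds) > d_mr, north_source


def shading_proportion(
    intervals: list[ShadingInterval] | tuple[ShadingInterval, ...],
    ctx: DayContext,
) -> float:
    """Shading proportion SP from shaded intervals via the sin(alpha) integral.

    Each interval contributes the integral of sin(alpha) d(alpha) along the
    elevation branch(es) it covers: cos(alpha_1) - cos(alpha_2) on a single
    monotone branch, or the sum of both branch pieces when it spans solar
    noon. The denominator covers the whole day, 2 (1 - cos(alpha_max)), since
    elevation is 0 at sunrise and sunset. Disjoint intervals sum.
    """
    ivs = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(ivs, ivs[1:]):
        if b.start < a.end - 1e-12:
            raise ValueError(f"overlapping intervals: {a} and {b}")
    amax = np.deg2rad(ctx.max_elevation)
    denom = 2.0 * (1.0 - np.cos(amax))
    if denom <= 0:
        return 0.0
    eps = 1e-9

    def cos_elev(t: float) -> float:
        if t <= ctx.sunrise_lst + eps or t >= ctx.sunset_lst - eps:
            return 1.0  # elevation 0 at the day boundaries
        return float(np.cos(np.deg2rad(ctx.elevation_at(t))))

    num = 0.0
    for iv in ivs:
        c1, c2 = cos_elev(iv.start), cos_elev(iv.end)
        if iv.end <= 12.0 or iv.start >= 12.0:
            num += abs(c1 - c2)  # single monotone branch
        else:
            num += (c1 - np.cos(amax)) + (c2 - np.cos(amax))  # spans solar noon
    return float(min(1.0, max(0.0, num / denom)))


def shading_capacity(sp: float, direct_radiation: float) -> float:
    """Daily shading capacity SC = R_a * SP (MJ m^-2)."""
    if not 0.0 <= sp <= 1.0:
        raise ValueError(f"SP must be in [0, 1], got {sp}")
    if direct_radiation < 0:
        raise ValueError(f"direct radiation must be >= 0, got {direct_radiation}")
    return sp * direct_radiation


def aggregate_strip(row_values, widths) -> float:
    """Width-weighted mean of per-row values (strip-level SP or SC)."""
    v = np.asarray(row_values, dtype=float)
    w = np.asarray(widths, dtype=float)
    if v.shape != w.shape:
        raise ValueError(f"row values and widths differ in length: {v.shape} vs {w.shape}")
    if np.any(w <= 0):
        raise ValueError("row widths must be positive")
    return float(np.sum(v * w) / np.sum(w))


def simulate_day(
    date: Date,
    layout: StripLayout,
    h_ms_north: float,
    h_ms_south: float,
    direct_radiation: float,
    step_minutes: float = 1.0,
    ctx: DayContext | None = None,
) -> tuple[list[DailyShadingResult], float, float]:
    """All rows for one day; returns (row results, SP_strip, SC_strip)."""
    if ctx is None:
        ctx = day_context(date.timetuple().tm_yday, layout.latitude)
    edges, alpha, beta = _day_grid(ctx, step_minutes)
    results = []
    for row in row_distances(layout):
        shaded, north_source = _shaded_mask(
            alpha, beta, layout.planting_direction, h_ms_north, h_ms_south,
            row.d_mr_north_source, row.d_mr_south_source,
        )
        ivs = _mask_to_intervals(shaded, north_source, edges)
        sp = shading_proportion(ivs, ctx)
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "%s R%d intervals: %s", date, row.row_index,
                [(round(iv.start, 3), round(iv.end, 3), iv.source) for iv in ivs],
            )
        results.append(
            DailyShadingResult(
                row_index=row.row_index,
                date=date,
                intervals=tuple(ivs),
                shading_time=float(sum(iv.duration for iv in ivs)),
                sp=sp,
                sc=shading_capacity(sp, direct_radiation),
            )
        )
    widths = layout.widths
    sp_strip = aggregate_strip([r.sp for r in results], widths)
    sc_strip = aggregate_strip([r.sc for r in results], widths)
    return results, sp_strip, sc_strip


def simulate_period(
    layout: StripLayout,
    h_ms: pd.DataFrame,
    direct_radiation: pd.Series,
    step_minutes: float = 1.0,
) -> CSCTable:
    """Run the SCM over a period and accumulate CSC.

    Parameters
    ----------
    h_ms:
        DataFrame indexed by date with columns ``north`` and ``south``
        (daily canopy-height differences, m).
    direct_radiation:
        Series indexed by date, daily R_a (MJ m^-2 day^-1); its dates must
        cover the h_ms index.
    """
    dates = [pd.Timestamp(d).date() for d in h_ms.index]
    missing = [d for d in dates if pd.Timestamp(d) not in direct_radiation.index]
    if missing:
        raise ValueError(f"direct radiation missing for dates: {missing[:5]}")
    daily: list[DailyShadingResult] = []
    strip_rows = []
    for d in dates:
        hn = float(h_ms.loc[pd.Timestamp(d), "north"])
        hs = float(h_ms.loc[pd.Timestamp(d), "south"])
        ra = float(direct_radiation.loc[pd.Timestamp(d)])
        results, sp_s, sc_s = simulate_day(d, layout, hn, hs, ra, step_minutes)
        daily.extend(results)
        strip_rows.append({"date": d, "SP_strip": sp_s, "SC_strip": sc_s})
    return cumulate(daily, pd.DataFrame(strip_rows))


def cumulate(daily: list[DailyShadingResult], strip: pd.DataFrame) -> CSCTable:
    """Accumulate daily SC into per-row and overall CSC over a contiguous period."""
    rows = pd.DataFrame(
        {
            "date": [r.date for r in daily],
            "row": [r.row_index for r in daily],
            "shading_time_h": [r.shading_time for r in daily],
            "SP": [r.sp for r in daily],
            "SC": [r.sc for r in daily],
        }
    )
    dates = sorted(set(rows["date"]))
    if dates:
        expected = {dates[0] + timedelta(days=k) for k in range((dates[-1] - dates[0]).days + 1)}
        gaps = sorted(expected - set(dates))
        if gaps:
            raise ValueError(f"period has gaps; missing dates: {gaps}")
    csc = rows.groupby("row")["SC"].sum()
    return CSCTable(
        rows=rows,
        strip=strip,
        csc_per_row=csc,
        overall_csc=float(strip["SC_strip"].sum()),
    )
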