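"""Configuration handling and the chm -> simulate pipeline glue.

A run is described by a YAML config (see :class:`RunConfig.from_yaml`) naming
the site, the strip layout, the simulation period, a weather CSV and an H_ms
source — either a ready-made CSV of daily canopy-height differences or a
directory of DSM/ortho rasters from which they are estimated. Outputs are
plain CSVs plus a JSON manifest echoing the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .canopy import (
    bimodal_threshold,
    chm,
    exg,
    height_difference,
    interpolate_daily,
    polygon_mask,
    read_polygons,
    read_raster,
    strip_height,
)
from .layout import StripLayout
from .radiation import partition_day, read_weather_csv
from .shading import CSCTable, simulate_period
from .solar import day_context

__all__ = [
    "RunConfig",
    "run_pipeline",
    "estimate_strip_heights",
    "hms_from_rasters",
    "read_hms_csv",
    "write_hms_csv",
    "direct_radiation_series",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one simulation run needs."""

    layout: StripLayout
    start: Date
    end: Date
    weather_csv: Path
    hms_source: str  # "csv" | "rasters"
    hms_path: Path  # CSV file, or directory of rasters
    output_dir: Path
    sowing: Date | None = None
    step_minutes: float = 1.0
    strip_id: str = "strip"
    height_threshold: float | None = None  # optional explicit maize/soybean cut (m)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        site = doc.get("site", {})
        lay = doc["layout"]
        layout = StripLayout(
            configuration=lay.get("configuration", "2M3S"),
            n_maize_rows=int(lay.get("n_maize_rows", 2)),
            n_soybean_rows=int(lay.get("n_soybean_rows", 3)),
            row_spacing=float(lay.get("row_spacing_m", 0.6)),
            strip_distance=float(lay.get("strip_distance_m", 0.6)),
            planting_direction=float(site.get("planting_direction_deg", lay.get("planting_direction_deg", 59.0))),
            latitude=float(site.get("latitude_deg", 43.267)),
        )
        period = doc["period"]
        hms = doc["h_ms"]
        base = Path(path).parent

        def _p(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        return cls(
            layout=layout,
            start=pd.Timestamp(period["start"]).date(),
            end=pd.Timestamp(period["end"]).date(),
            sowing=pd.Timestamp(period["sowing"]).date() if "sowing" in period else None,
            weather_csv=_p(doc["weather"]),
            hms_source=hms["source"],
            hms_path=_p(hms["path"]),
            output_dir=_p(doc.get("output_dir", "out")),
            step_minutes=float(doc.get("step_minutes", 1.0)),
            height_threshold=doc.get("height_threshold_m"),
            seed=int(doc.get("seed", 0)),
        )


def read_hms_csv(path: str | Path, strip_id: str | None = None) -> pd.DataFrame:
    """Read an H_ms series CSV ``date,strip_id,side,H_ms_m`` into a frame
    indexed by date with columns ``north``/``south``."""
    df = pd.read_csv(path, parse_dates=["date"])
    if strip_id is not None:
        df = df[df["strip_id"] == strip_id]
    wide = df.pivot(index="date", columns="side", values="H_ms_m").sort_index()
    missing = {"north", "south"} - set(wide.columns)
    if missing:
        raise ValueError(f"H_ms CSV lacks sides: {sorted(missing)}")
    return wide[["north", "south"]]


def write_hms_csv(path: str | Path, h_ms: pd.DataFrame, strip_id: str = "strip") -> None:
    long = h_ms.reset_index().melt(id_vars="index", var_name="side", value_name="H_ms_m")
    long = long.rename(columns={"index": "date"})
    long.insert(1, "strip_id", strip_id)
    long.sort_values(["date", "side"]).to_csv(path, index=False)


def estimate_strip_heights(
    reference,
    dsm,
    ortho,
    polygons: dict,
    crops: dict[str, str],
    height_threshold: float | None = None,
) -> dict[str, float]:
    """Per-strip canopy heights for one flight date.

    EXG soil masking on the ortho, CHM from the DSM pair, then the crop
    percentile within each strip polygon. Within soybean strips, pixels above
    the maize/soybean height threshold (estimated from the CHM histogram when
    not supplied) are treated as overhanging maize and excluded; within maize
    strips the short class is excluded symmetrically.
    """
    bands = ortho.data.astype(float)
    veg = exg(bands[..., 0], bands[..., 1], bands[..., 2])
    veg_mask = veg > bimodal_threshold(veg)
    canopy = chm(dsm, reference)
    if height_threshold is None:
        try:
            height_threshold = bimodal_threshold(canopy.data[veg_mask])
        except ValueError:
            height_threshold = None  # single species visible; no cut needed
    heights = {}
    for strip_id, poly in polygons.items():
        crop = crops[strip_id]
        mask = polygon_mask(canopy, poly) & veg_mask
        values = canopy.data[mask]
        if height_threshold is not None:
            values = values[values > height_threshold] if crop == "maize" else values[values <= height_threshold]
        heights[strip_id] = strip_height(values, crop)
    return heights


def hms_from_rasters(
    raster_dir: str | Path,
    height_threshold: float | None = None,
    strip_id: str = "strip",
) -> pd.DataFrame:
    """Estimate a daily H_ms frame from a directory of flight rasters.

    Expects ``reference.tif``, ``strips.geojson`` and per-date pairs
    ``dsm_YYYY-MM-DD.tif`` / ``ortho_YYYY-MM-DD.tif``; the GeoJSON must
    contain strips named ``maize_north``, ``maize_south`` and ``soybean``.
    """
    d = Path(raster_dir)
    reference = read_raster(d / "reference.tif")
    polygons = read_polygons(d / "strips.geojson")
    crops = {k: ("maize" if k.startswith("maize") else "soybean") for k in polygons}
    dates, per_strip = [], {k: [] for k in polygons}
    for dsm_path in sorted(d.glob("dsm_*.tif")):
        date = pd.Timestamp(dsm_path.stem.removeprefix("dsm_")).date()
        ortho_path = d / f"ortho_{date.isoformat()}.tif"
        heights = estimate_strip_heights(
            reference, read_raster(dsm_path), read_raster(ortho_path),
            polygons, crops, height_threshold,
        )
        dates.append(date)
        for k, v in heights.items():
            per_strip[k].append(v)
    if len(dates) < 3:
        raise ValueError(f"need at least 3 flight dates for spline interpolation, found {len(dates)}")
    daily = {k: interpolate_daily(dates, np.asarray(v)) for k, v in per_strip.items()}
    series = height_difference(
        daily["maize_north"], daily["maize_south"], daily["soybean"], strip_id=strip_id
    )
    return series.frame()


def direct_radiation_series(weather_csv: str | Path, latitude: float) -> pd.Series:
    """Daily direct radiation R_a (MJ m^-2) from a weather CSV."""
    days = read_weather_csv(weather_csv)
    idx, vals = [], []
    for w in days:
        ctx = day_context(w.date.timetuple().tm_yday, latitude)
        idx.append(pd.Timestamp(w.date))
        vals.append(partition_day(w, ctx).direct)
    return pd.Series(vals, index=pd.DatetimeIndex(idx), name="Ra")


def run_pipeline(config: RunConfig) -> CSCTable:
    """Execute the full chm -> radiation -> shading pipeline and write outputs."""
    logger.info("stage: H_ms (%s)", config.hms_source)
    if config.hms_source == "csv":
        h_ms = read_hms_csv(config.hms_path)
    elif config.hms_source == "rasters":
        h_ms = hms_from_rasters(config.hms_path, config.height_threshold, config.strip_id)
    else:
        raise ValueError(f"unknown H_ms source {config.hms_source!r}")
    h_ms = h_ms.loc[pd.Timestamp(config.start) : pd.Timestamp(config.end)]
    if h_ms.empty:
        raise ValueError("period does not overlap the H_ms series")

    logger.info("stage: radiation")
    ra = direct_radiation_series(config.weather_csv, config.layout.latitude)

    logger.info("stage: shading model (%d days)", len(h_ms))
    table = simulate_period(config.layout, h_ms, ra, config.step_minutes)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.rows.to_csv(out / "rows.csv", index=False)
    table.strip.to_csv(out / "strip.csv", index=False)
    summary = table.csc_per_row.rename("CSC").reset_index()
    summary.to_csv(out / "summary.csv", index=False)
    manifest = {
        "package": "stripshade",
        "version": __version__,
        "config": {
            **{k: str(v) for k, v in asdict(config).items() if k != "layout"},
            "layout": asdict(config.layout),
        },
        "overall_csc": table.overall_csc,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("wrote outputs to %s (overall CSC = %.2f MJ m^-2)", out, table.overall_csc)
    return table
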