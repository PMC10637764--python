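"""Canopy-height differences from UAV surface models.

Pipeline: a canopy height model (CHM) is the per-pixel difference between a
crop-stage digital surface model (DSM) and the bare-ground reference DSM
flown before emergence. Soil pixels are removed with the excess-green index
(EXG = 2g - r - b) thresholded at the local minimum of its bimodal histogram;
maize and soybean pixels are then separated by a height threshold (again the
histogram local minimum, or a supplied per-stage value). Strip canopy height
is a high percentile of the masked CHM values — 99.9th for maize (open,
spiky canopy) and 90th for soybean (closed canopy). Heights measured on a
few flight dates are interpolated to a daily curve with a natural cubic
spline, and the daily canopy-height difference H_ms is maize minus soybean,
kept separately for the strips north and south of each soybean strip.

Rasters are plain single-band float TIFFs (or in-memory grids) with a pixel
size in metres; strip footprints are shapely polygons in the same ground
coordinate frame (GeoJSON on disk).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date as Date
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d
from shapely.geometry import shape as shapely_shape
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry.base import BaseGeometry
from shapely import contains_xy

__all__ = [
    "RasterGrid",
    "HeightDifferenceSeries",
    "exg",
    "bimodal_threshold",
    "chm",
    "separate_species",
    "strip_height",
    "interpolate_daily",
    "height_difference",
    "r_squared",
    "rmse",
    "polygon_mask",
    "read_raster",
    "write_raster",
    "read_polygons",
    "write_polygons",
]

MAIZE_PERCENTILE = 99.9
SOYBEAN_PERCENTILE = 90.0


@dataclass
class RasterGrid:
    """A georeferenced grid: ``data[i, j]`` at ground position
    ``(origin_x + (j + 0.5) * pixel_size, origin_y - (i + 0.5) * pixel_size)``
    (row 0 is the northern edge, as in imagery)."""

    data: np.ndarray
    pixel_size: float  # m / pixel
    origin: tuple[float, float] = (0.0, 0.0)  # ground (x, y) of the top-left corner

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.pixel_size <= 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Ground coordinates (x, y) of every pixel center, as 2-D arrays."""
        ny, nx = self.data.shape[:2]
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size
        ys = self.origin[1] - (np.arange(ny) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)


def exg(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Excess-green index per pixel: ``EXG = 2g - r - b``."""
    r, g, b = (np.asarray(c, dtype=float) for c in (r, g, b))
    if not (r.shape == g.shape == b.shape):
        raise ValueError(f"band shapes differ: {r.shape}, {g.shape}, {b.shape}")
    if (r < 0).any() or (g < 0).any() or (b < 0).any():
        raise ValueError("digital numbers must be >= 0")
    return 2.0 * g - r - b


def bimodal_threshold(values: np.ndarray, bins: int = 128, smooth_bins: float = 2.0) -> float:
    """Local-minimum threshold between the two modes of a bimodal histogram.

    The histogram is lightly Gaussian-smoothed (sigma in bins) before the
    search; the threshold is the lowest point between the two tallest
    separated peaks. Raises if no two distinct modes are found.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("histogram is degenerate (constant values); supply a manual threshold")
    counts, edges = np.histogram(v, bins=bins)
    smoothed = gaussian_filter1d(counts.astype(float), smooth_bins)
    # local maxima of the smoothed histogram
    interior = (smoothed[1:-1] >= smoothed[:-2]) & (smoothed[1:-1] > smoothed[2:])
    peaks = np.flatnonzero(interior) + 1
    if smoothed[0] > smoothed[1]:
        peaks = np.r_[0, peaks]
    if smoothed[-1] > smoothed[-2]:
        peaks = np.r_[peaks, smoothed.size - 1]
    if peaks.size < 2:
        raise ValueError("histogram appears unimodal; supply a manual threshold")
    top2 = peaks[np.argsort(smoothed[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    if hi - lo < 2:
        raise ValueError("histogram modes are not separated; supply a manual threshold")
    valley = lo + 1 + int(np.argmin(smoothed[lo + 1 : hi]))
    # the dip must be pronounced, or the "modes" are just histogram noise
    if smoothed[valley] > 0.75 * min(smoothed[lo], smoothed[hi]):
        raise ValueError("histogram appears unimodal; supply a manual threshold")
    return float(0.5 * (edges[valley] + edges[valley + 1]))


def chm(dsm: RasterGrid, reference: RasterGrid) -> RasterGrid:
    """Canopy height model: ``CHM = DSM - H_g``, negatives clipped to 0.

    Below-reference values are photogrammetric noise and carry no canopy
    information.
    """
    if dsm.shape != reference.shape:
        raise ValueError(f"DSM shape {dsm.shape} != reference shape {reference.shape}")
    if not np.isclose(dsm.pixel_size, reference.pixel_size):
        raise ValueError("DSM and reference pixel sizes differ")
    if not np.allclose(dsm.origin, reference.origin):
        raise ValueError("DSM and reference origins differ")
    return RasterGrid(
        data=np.clip(dsm.data - reference.data, 0.0, None),
        pixel_size=dsm.pixel_size,
        origin=dsm.origin,
    )


def separate_species(
    chm_values: np.ndarray, height_threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split soil-masked CHM values into (maize, soybean) by a height cut."""
    v = np.asarray(chm_values, dtype=float)
    maize = v[v > height_threshold]
    soybean = v[v <= height_threshold]
    if maize.size == 0 or soybean.size == 0:
        import warnings

        warnings.warn(
            f"species separation at {height_threshold} m left an empty class "
            f"(maize {maize.size}, soybean {soybean.size} pixels)",
            stacklevel=2,
        )
    return maize, soybean


def strip_height(chm_values: np.ndarray, crop: str) -> float:
    """Strip canopy height (m): the crop-specific percentile of CHM values.

    99.9th percentile for maize, 90th for soybean (linear-interpolation
    percentile); the lower soybean quantile reflects its closed canopy.
    """
    v = np.asarray(chm_values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty pixel set after masking; cannot extract a strip height")
    if crop == "maize":
        q = MAIZE_PERCENTILE
    elif crop == "soybean":
        q = SOYBEAN_PERCENTILE
    else:
        raise ValueError(f"crop must be 'maize' or 'soybean', got {crop!r}")
    return float(np.percentile(v, q))


def interpolate_daily(dates: list[Date], heights: np.ndarray) -> pd.Series:
    """Natural cubic spline through measured heights, evaluated daily.

    Returns a Series indexed by every day from the first to the last
    measurement. No extrapolation: request values only inside the range.
    """
    if len(dates) < 3:
        raise ValueError("need at least 3 measurement dates for a cubic spline")
    days = np.array([(d - dates[0]).days for d in dates], dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("measurement dates must be strictly increasing")
    h = np.asarray(heights, dtype=float)
    if h.shape != days.shape:
        raise ValueError("dates and heights differ in length")
    spline = CubicSpline(days, h, bc_type="natural")
    grid = np.arange(0, days[-1] + 1)
    idx = pd.DatetimeIndex([pd.Timestamp(dates[0]) + pd.Timedelta(days=int(k)) for k in grid])
    return pd.Series(spline(grid), index=idx)


@dataclass
class HeightDifferenceSeries:
    """Daily canopy-height differences H_ms for one soybean strip."""

    strip_id: str
    north: pd.Series  # daily H_ms to the northern maize strip (m)
    south: pd.Series  # daily H_ms to the southern maize strip (m)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"north": self.north, "south": self.south})


def height_difference(
    maize_daily_north: pd.Series,
    maize_daily_south: pd.Series,
    soybean_daily: pd.Series,
    strip_id: str = "strip",
) -> HeightDifferenceSeries:
    """H_ms per side: adjacent maize height minus soybean height, clipped at 0."""
    for name, s in (("north", maize_daily_north), ("south", maize_daily_south)):
        if not s.index.equals(soybean_daily.index):
            raise ValueError(f"{name} maize series dates are not aligned with the soybean series")
    import warnings

    out = {}
    for name, s in (("north", maize_daily_north), ("south", maize_daily_south)):
        diff = s - soybean_daily
        if (diff < 0).any():
            warnings.warn(
                f"negative H_ms on the {name} side clipped to 0 "
                f"(soybean taller than maize on {int((diff < 0).sum())} days)",
                stacklevel=2,
            )
        out[name] = diff.clip(lower=0.0)
    return HeightDifferenceSeries(strip_id=strip_id, north=out["north"], south=out["south"])


def r_squared(estimated: np.ndarray, measured: np.ndarray) -> float:
    """Coefficient of determination as the ratio of sums of squares,
    ``sum((x_hat - x_bar)^2) / sum((x - x_bar)^2)``.

    Note this is the regression-sum-of-squares form, not 1 - SS_res/SS_tot;
    it can exceed 1 when the estimates are more spread than the measurements.
    """
    est, meas = _paired(estimated, measured)
    xbar = meas.mean()
    denom = np.sum((meas - xbar) ** 2)
    if denom == 0:
        raise ValueError("measured values have zero variance; R^2 is undefined")
    return float(np.sum((est - xbar) ** 2) / denom)


def rmse(estimated: np.ndarray, measured: np.ndarray) -> float:
    """Root mean square error (same units as the inputs)."""
    est, meas = _paired(estimated, measured)
    return float(np.sqrt(np.mean((est - meas) ** 2)))


def _paired(estimated, measured) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimated, dtype=float).ravel()
    meas = np.asarray(measured, dtype=float).ravel()
    if est.shape != meas.shape:
        raise ValueError(f"paired vectors differ in length: {est.shape} vs {meas.shape}")
    if est.size < 2:
        raise ValueError("need at least 2 paired observations")
    return est, meas


# ---------------------------------------------------------------------------
# raster / vector I/O and zonal extraction


def polygon_mask(grid: RasterGrid, polygon: BaseGeometry) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon."""
    xx, yy = grid.pixel_centers()
    return contains_xy(polygon, xx, yy)


def write_raster(path: str | Path, grid: RasterGrid) -> None:
    """Write a grid as a single- or multi-band float32/uint8 TIFF with the
    geo transform stored in the image description."""
    import tifffile

    meta = json.dumps({"pixel_size": grid.pixel_size, "origin": list(grid.origin)})
    tifffile.imwrite(str(path), grid.data, description=meta)


def read_raster(path: str | Path) -> RasterGrid:
    """Read a TIFF written by :func:`write_raster`."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {"pixel_size": 1.0, "origin": [0, 0]}
    return RasterGrid(data=data, pixel_size=meta["pixel_size"], origin=tuple(meta["origin"]))


def write_polygons(path: str | Path, polygons: dict[str, BaseGeometry]) -> None:
    """Write named strip footprints as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "properties": {"strip_id": k}, "geometry": shapely_mapping(p)}
        for k, p in polygons.items()
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_polygons(path: str | Path) -> dict[str, BaseGeometry]:
    """Read strip footprints from GeoJSON keyed by the ``strip_id`` property."""
    doc = json.loads(Path(path).read_text())
    return {
        f["properties"]["strip_id"]: shapely_shape(f["geometry"]) for f in doc["features"]
    }
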