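"""Synthetic inputs for exercising the full pipeline without field data.

Three generators, all deterministic under a fixed seed:

* :func:`make_scene` — a DSM pair (bare-ground reference + crop stage), a
  3-band ortho image and strip polygons for a maize/soybean/maize block, with
  the per-strip true heights recorded alongside.
* :func:`make_weather` — a plausible daily weather series (R_g, S) for a site,
  bounded by the astronomical limits of each date.
* :func:`make_growth` — logistic canopy-height trajectories for both crops
  sampled at the measurement dates, emulating the rise / plateau / rise shape
  of the vegetative-season height-difference curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd
from shapely.geometry import box

from .canopy import HeightDifferenceSeries, RasterGrid, height_difference, interpolate_daily
from .layout import StripLayout
from .radiation import DailyWeather, extraterrestrial_radiation
from .solar import day_context

__all__ = [
    "SceneSpec",
    "GrowthSpec",
    "Scene",
    "make_scene",
    "make_weather",
    "make_growth",
    "growth_height_series",
    "DEFAULT_SOWING_DATE",
    "MEASUREMENT_DAS",
]

#: Sowing date of the experiment the defaults emulate.
DEFAULT_SOWING_DATE = Date(2021, 5, 25)
#: Days after sowing of the four canopy-height measurements.
MEASUREMENT_DAS = (41, 48, 56, 64)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic DSM/ortho scene."""

    layout: StripLayout = field(default_factory=StripLayout)
    maize_height: float = 1.8  # true canopy-top height (m)
    soybean_height: float = 0.7
    noise_sigma: float = 0.02  # photogrammetric height noise (m)
    maize_relief: float = 0.15  # Rayleigh scale of the open maize canopy's surface dips (m)
    pixel_size: float = 0.025  # m/pixel (coarser than a real UAV survey)
    scene_width: float = 4.0  # east-west extent (m)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.maize_height <= 0 or self.soybean_height <= 0:
            raise ValueError("true canopy heights must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class Scene:
    """A generated scene plus its ground truth."""

    reference: RasterGrid  # bare-ground DSM
    dsm: RasterGrid  # crop-stage DSM
    ortho: RasterGrid  # 3-band uint8 (r, g, b)
    polygons: dict  # strip_id -> shapely polygon (ground coordinates)
    truth: pd.DataFrame  # columns: strip_id, crop, height_m
    vegetation_mask: np.ndarray  # true vegetation pixels (for mask scoring)


def make_scene(spec: SceneSpec) -> Scene:
    """Build a maize / soybean / maize block scene with known heights.

    Strips run east-west across the full scene width; from north to south:
    maize strip, gap D_ms, soybean strip, gap D_ms, maize strip. The crop DSM
    adds canopies on the flat (noisy) ground of the reference DSM. The maize
    surface dips below its canopy-top height with Rayleigh-distributed relief
    (an open, spiky canopy: only a thin crest sits at the true height, which
    is what the 99.9th-percentile extraction is designed to find), while the
    closed soybean canopy is level at its height. The ortho colours
    vegetation green-dominant and soil brown so that EXG masking is
    exercised.
    """
    rng = np.random.default_rng(spec.seed)
    lay = spec.layout
    maize_w = lay.n_maize_rows * lay.row_spacing
    soy_w = lay.n_soybean_rows * lay.row_spacing
    if maize_w <= 0 or soy_w <= 0:
        raise ValueError("degenerate layout: zero-width strips")
    margin = 0.3
    total_h = 2 * margin + 2 * maize_w + 2 * lay.strip_distance + soy_w
    ny = int(round(total_h / spec.pixel_size))
    nx = int(round(spec.scene_width / spec.pixel_size))
    px = spec.pixel_size

    ground = 100.0 + rng.normal(0.0, spec.noise_sigma, size=(ny, nx))
    canopy = np.zeros((ny, nx))
    # y measured downward from the northern edge
    bands = [
        ("maize_north", "maize", margin, margin + maize_w, spec.maize_height),
        ("soybean", "soybean", margin + maize_w + lay.strip_distance,
         margin + maize_w + lay.strip_distance + soy_w, spec.soybean_height),
        ("maize_south", "maize",
         margin + maize_w + 2 * lay.strip_distance + soy_w,
         margin + 2 * maize_w + 2 * lay.strip_distance + soy_w, spec.maize_height),
    ]
    yc = (np.arange(ny) + 0.5) * px
    polygons = {}
    truth_rows = []
    for strip_id, crop, y0, y1, h in bands:
        rows = (yc >= y0) & (yc < y1)
        block = np.full((int(rows.sum()), nx), h)
        if crop == "maize":
            dips = np.minimum(spec.maize_relief * rng.weibull(2.0, block.shape), 0.4 * h)
            block -= dips
        canopy[rows, :] = block
        # ground frame: y increases northward from the southern edge
        polygons[strip_id] = box(0.0, total_h - y1, spec.scene_width, total_h - y0)
        truth_rows.append({"strip_id": strip_id, "crop": crop, "height_m": h})

    dsm_data = ground + canopy + rng.normal(0.0, spec.noise_sigma, size=(ny, nx))
    veg = canopy > 0

    # ortho: green-dominant vegetation on brown soil, mild DN noise
    r = np.where(veg, 60, 120) + rng.normal(0, 8, (ny, nx))
    g = np.where(veg, 150, 100) + rng.normal(0, 8, (ny, nx))
    b = np.where(veg, 55, 80) + rng.normal(0, 8, (ny, nx))
    ortho = np.clip(np.stack([r, g, b], axis=-1), 0, 255).astype(np.uint8)

    origin = (0.0, total_h)  # top-left corner in ground coordinates
    return Scene(
        reference=RasterGrid(ground, px, origin),
        dsm=RasterGrid(dsm_data, px, origin),
        ortho=RasterGrid(ortho, px, origin),
        polygons=polygons,
        truth=pd.DataFrame(truth_rows),
        vegetation_mask=veg,
    )


def make_weather(
    n_days: int,
    latitude: float = 43.267,
    start_date: Date | None = None,
    seed: int = 0,
) -> list[DailyWeather]:
    """A plausible daily weather series bounded by astronomical limits.

    Daily clearness index is drawn uniformly in [0.3, 0.75] (overcast to
    clear) and the sunshine fraction follows it with noise, so R_g <= R_0 and
    0 <= S <= S_0 by construction.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if start_date is None:
        start_date = DEFAULT_SOWING_DATE + timedelta(days=MEASUREMENT_DAS[0])
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_days):
        d = start_date + timedelta(days=k)
        doy = d.timetuple().tm_yday
        ctx = day_context(doy, latitude)
        r0 = extraterrestrial_radiation(doy, latitude)
        clearness = rng.uniform(0.3, 0.75)
        s_frac = np.clip((clearness - 0.25) / 0.5 + rng.normal(0, 0.1), 0.0, 1.0)
        out.append(
            DailyWeather(
                date=d,
                global_radiation=clearness * r0,
                sunshine_duration=float(s_frac * ctx.max_sunshine_duration),
            )
        )
    return out


@dataclass(frozen=True)
class GrowthSpec:
    """Logistic canopy-growth parameters for the two crops.

    Height at t days after sowing is ``A / (1 + exp(-k (t - t0)))``. The
    defaults make maize elongate steadily through the measurement window
    (reaching ~2.5 m at tasseling; the asymptote sits above because
    elongation has not finished by then) while soybean has its growth spurt
    mid-window, so the height difference H_ms rises quickly, plateaus, then
    rises again — the characteristic vegetative-season shape — and stays
    positive throughout.
    """

    maize_asymptote: float = 3.4  # m (logistic ceiling, not the height reached in-window)
    maize_rate: float = 0.08  # day^-1
    maize_inflection: float = 52.0  # DAS
    soybean_asymptote: float = 0.95
    soybean_rate: float = 0.32
    soybean_inflection: float = 52.0
    measurement_das: tuple[int, ...] = MEASUREMENT_DAS
    north_south_offset: float = 0.01  # m, slight asymmetry between sides
    noise_sigma: float = 0.0  # measurement noise (m)
    seed: int = 0


def _logistic(t: np.ndarray, a: float, k: float, t0: float) -> np.ndarray:
    return a / (1.0 + np.exp(-k * (t - t0)))


def make_growth(spec: GrowthSpec) -> pd.DataFrame:
    """Measured canopy heights at the measurement dates.

    Returns a frame with columns ``das, maize_north, maize_south, soybean``
    (heights in m). The north and south maize strips differ by a small fixed
    offset, mirroring the slight side asymmetry seen in the field.
    """
    rng = np.random.default_rng(spec.seed)
    das = np.asarray(spec.measurement_das, dtype=float)
    maize = _logistic(das, spec.maize_asymptote, spec.maize_rate, spec.maize_inflection)
    soy = _logistic(das, spec.soybean_asymptote, spec.soybean_rate, spec.soybean_inflection)
    noise = lambda: rng.normal(0.0, spec.noise_sigma, das.size) if spec.noise_sigma else 0.0
    frame = pd.DataFrame(
        {
            "das": das.astype(int),
            "maize_north": maize + spec.north_south_offset / 2 + noise(),
            "maize_south": maize - spec.north_south_offset / 2 + noise(),
            "soybean": soy + noise(),
        }
    )
    if (frame[["maize_north", "maize_south", "soybean"]] <= 0).any().any():
        raise ValueError("growth spec produced non-positive heights")
    return frame


def growth_height_series(
    spec: GrowthSpec,
    sowing_date: Date = DEFAULT_SOWING_DATE,
    strip_id: str = "strip",
) -> tuple[HeightDifferenceSeries, pd.Series]:
    """Daily H_ms series (and soybean heights) from a growth spec.

    Splines each measured trajectory to a daily curve and differences maize
    against soybean per side — the same path field measurements take.
    """
    frame = make_growth(spec)
    dates = [sowing_date + timedelta(days=int(d)) for d in frame["das"]]
    mn = interpolate_daily(dates, frame["maize_north"].to_numpy())
    ms = interpolate_daily(dates, frame["maize_south"].to_numpy())
    sb = interpolate_daily(dates, frame["soybean"].to_numpy())
    return height_difference(mn, ms, sb, strip_id=strip_id), sb
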