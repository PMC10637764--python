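# Methods

## Model overview and assumptions

The shading capacity model treats each maize strip as an opaque cuboid whose
height exceeds the adjacent soybean canopy by H_ms (m). Its assumptions, all
deliberate simplifications:

- Weather is uniform within a day; the daily direct radiation R_a is spread
  over the day following the sinusoidal intensity proxy I_s = sin α, so the
  fraction of the day's direct energy falling in a time window is the ratio
  of ∫ sin α dα integrals along the solar-elevation branches.
- Only the direct beam matters: diffuse light casts no well-defined shadow
  and is ignored, as is transmission through the maize canopy.
- Local solar time drives the hour angle directly; no equation-of-time or
  longitude correction is applied (a 4 min-per-degree helper exists for
  callers with clock-time data). Solar position uses the classic daily
  formulas (Cooper declination, spherical-triangle azimuth), adequate at the
  sub-degree level the 1-minute scan needs; refraction is ignored.
- Shading is evaluated against row *positions*, not canopy volumes: a row is
  shaded at an instant iff the signed shadow reach |D_s| exceeds its origin
  distance D_mr on the active source side.

## Geometry conventions

Soybean rows are indexed R1..Rn from south to north. The shading origin is
the midpoint between the soybean strip and whichever maize strip casts the
shadow, so row i has D_mr = D_ms/2 + (i−1)·D_r from the southern source and
D_ms/2 + (n−i)·D_r from the northern source. The planting direction γ is
counterclockwise from north and axial (stored modulo 180°); azimuth β is
clockwise from north with the morning branch < 180°. The sign of
cos(β + γ − 90°) alone selects the source strip, since tan α and H_ms are
positive in daylight. At solar noon with N–S rows the cosine vanishes:
shadows run along the rows, no cross-row shading — the check that fixes the
sign convention.

Row widths w_i weight the strip aggregation SP_strip = Σ SP_i w_i / Σ w_i.
They default to D_r for every row (making strip values plain row means),
because the uniform 0.6 m row spacing of the motivating design gives no
reason to weight rows unequally; a per-row width vector can be supplied.

## Numerical choices

- Time step: 1 min (configurable). Steps are evaluated at midpoints;
  interval endpoints snap to step edges. The convergence test shows halving
  the step moves seasonal CSC by well under 0.5%.
- SP branch bookkeeping: an interval wholly before or after solar noon
  contributes |cos α(t₁) − cos α(t₂)|; one spanning noon contributes
  (cos α(t₁) − cos α_max) + (cos α(t₂) − cos α_max). Boundary elevations are
  0 only when the boundary is sunrise/sunset. Disjoint intervals sum — a
  row can be shaded by the north strip in the morning and the south strip
  later, so multi-interval days are the norm, not the exception. The result
  is clamped to [0, 1].
- Arcsine/arccosine arguments are clamped to [−1, 1] (tolerance 1e-9) to
  guard the sunrise/sunset ends. At exactly ω = 0 the azimuth uses the
  morning-branch limit (180° for a noon sun due south).
- The extraterrestrial-radiation bracket mixes units by construction: the
  additive ω_s term must be in radians. This is handled (and tested)
  explicitly because it is the classic failure mode of the formula.
- The diffuse-fraction polynomial 1.06 − 0.56k − 0.11k² − 0.26s − 1.6s² is
  an empirical regression and is clamped to [0, 1]; near k ≈ 0.5, s ≈ 0.6 it
  approaches 0, i.e. almost fully direct days. Sunshine durations exceeding
  the astronomical maximum are clipped with a warning (recorder quirk), not
  rejected. The direct component is computed first and the diffuse part
  re-derived from it so R_d + R_a reproduces R_g bit-exactly.
- R² is implemented as Σ(x̂−x̄)²/Σ(x−x̄)² — the regression-sum-of-squares
  ratio, which can exceed 1 — matching the convention of the canopy-height
  validation it serves; this is not 1 − SS_res/SS_tot.
- Percentiles use linear interpolation between order statistics. The cubic
  spline for daily heights is natural (zero end curvature) and never
  extrapolates beyond the measurement window.
- CHM negatives are clipped to 0 (photogrammetric noise below ground);
  negative H_ms is clipped to 0 with a warning.

## Synthetic data: what it emulates, what it does not

The generators are first-class code and define the package's test
conditions.

**Scenes** (`make_scene`): a maize/soybean/maize block, strips running
east–west, ground at 100 m elevation, Gaussian height noise (default
σ = 0.02 m, a typical UAV photogrammetry figure), 0.025 m pixels (coarser
than a real survey's ~5 mm; the pipeline is resolution-agnostic). The maize
surface dips below its canopy-top height with Rayleigh-distributed relief
(scale 0.15 m): an open, spiky canopy in which only a thin crest reaches the
true height — which is precisely why the 99.9th-percentile extractor is the
right estimator for maize, while the closed soybean canopy is level and
takes the 90th. A flat-topped maize slab would make the 99.9th percentile of
the noise a ~3σ-biased max statistic and misrepresent the estimator the
pipeline actually uses. Not emulated: photogrammetric doming/blur, weeds,
gaps within strips, georeferencing error — so passing tests validate the
masking/percentile/spline logic, not robustness to survey artefacts.

**Growth** (`make_growth`): logistic canopy heights per crop, measured at
41/48/56/64 days after sowing (sown 25 May). Defaults — maize asymptote
3.4 m (a ceiling; ~2.5 m is reached in-window at tasseling), rate
0.08 day⁻¹, inflection 52 DAS; soybean 0.95 m, 0.32 day⁻¹, 52 DAS — chosen
so maize elongates steadily while soybean has its mid-window spurt, giving
the characteristic rise/plateau/rise of the H_ms curve (≈1.0 → 1.5 m) with
H_ms > 0 throughout. A small fixed north–south offset (1 cm) mirrors the
slight side asymmetry of real strips.

**Weather** (`make_weather`): daily clearness index uniform in [0.3, 0.75]
with the sunshine fraction tracking it plus noise, so R_g ≤ R_0 and
0 ≤ S ≤ S_0 by construction. No autocorrelation or seasonality beyond the
astronomical envelope.

## Sensitivity sweeps

Sweeps vary one input (constant H_ms 0–3 m; direction 0–180° at 1°; latitude
23.267–53.267° at 1°) holding the growth series fixed — the same H_ms is
reused at every latitude, isolating geometry from phenology. Reported value:
the unweighted mean over days of SP_strip (a radiation-weighted mean would
need a weather series and is left to callers). All solar geometry is
recomputed per latitude; grid points hitting polar day/night are flagged
with NaN rather than dropped.

## Problem sizes

Tests and examples run 24-day seasons (the 41–64 DAS measurement window) on
2M3S/3M6S layouts at the 1-minute step, and 30–40 k-pixel scenes; a single
season simulation takes ~10 ms, the full 181-point direction sweep a few
seconds.

## Known limitations

- The diffuse-fraction coefficients are a site-specific regression (Jilin);
  the latitude sweep applies them everywhere unchanged.
- Shading of maize by maize, PAR-specific bookkeeping, within-canopy
  transmission and any growth response to shading are out of scope.
- The accumulation window for CSC is whatever period the caller supplies;
  no default growth window is imposed.
- Automatic strip segmentation from the ortho-mosaic is not provided; strip
  footprints are supplied as polygons.
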