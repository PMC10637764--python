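"""Independent numerical oracles used by the unit and acceptance tests."""

import numpy as np

from stripshade.shading import ShadingInterval
from stripshade.solar import DayContext


def riemann_sp(intervals, ctx: DayContext, dt_seconds: float = 1.0) -> float:
    """Shading proportion by brute-force integration of sin(alpha) d(alpha).

    Walks the day at a fine time step accumulating |delta cos(alpha)| (the
    exact per-step integral of sin(alpha) d(alpha) along the monotone
    elevation branches), inside the shaded intervals for the numerator and
    over the whole day for the denominator. Independent of the closed-form
    branch bookkeeping in the implementation.
    """
    dt = dt_seconds / 3600.0
    t = np.arange(ctx.sunrise_lst, ctx.sunset_lst + dt / 2, dt)
    t[-1] = min(t[-1], ctx.sunset_lst)
    cosa = np.cos(np.deg2rad(np.asarray(ctx.elevation_at(t))))
    dcos = np.abs(np.diff(cosa))
    mid = 0.5 * (t[:-1] + t[1:])
    denom = dcos.sum()
    num = 0.0
    for iv in intervals:
        sel = (mid >= iv.start) & (mid <= iv.end)
        num += dcos[sel].sum()
    return float(num / denom)


def random_interval_set(ctx: DayContext, rng: np.random.Generator) -> list[ShadingInterval]:
    """Random disjoint daylight intervals (1 to 3) for oracle comparisons."""
    k = int(rng.integers(1, 4))
    points = np.sort(rng.uniform(ctx.sunrise_lst, ctx.sunset_lst, 2 * k))
    out = []
    for a, b in zip(points[0::2], points[1::2]):
        if b - a > 0.05:  # skip degenerate slivers
            out.append(ShadingInterval(float(a), float(b), "north"))
    return out
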