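"""Per-row shading for one mid-season day in a 2M3S strip layout.

With a 1.2 m canopy-height difference on both sides, prints each soybean
row's shaded intervals, cumulative shading time, shading proportion SP and
shading capacity SC, plus the width-weighted strip aggregates.
"""

from datetime import date

from stripshade import StripLayout, simulate_day

layout = StripLayout()  # 2M3S, D_r = D_ms = 0.6 m, gamma = 59 deg, 43.267 N
results, sp_strip, sc_strip = simulate_day(
    date(2021, 7, 20), layout, h_ms_north=1.2, h_ms_south=1.2, direct_radiation=17.0
)
for r in results:
    spans = ", ".join(f"{iv.start:5.2f}-{iv.end:5.2f}h ({iv.source})" for iv in r.intervals)
    print(f"R{r.row_index}: shaded {r.shading_time:5.2f} h  SP={r.sp:.3f}  "
          f"SC={r.sc:5.2f} MJ m^-2   [{spans}]")
print(f"strip: SP={sp_strip:.3f}  SC={sc_strip:.2f} MJ m^-2")
print("R1 (southernmost) is shaded longest: it sits closest to the southern")
print("maize strip, whose afternoon shadow covers the high-sun hours.")
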