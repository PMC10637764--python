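"""Solar position and daily radiation partitioning for one site and date.

Computes the per-day solar context at 43.267 deg N on July 20 and splits a
measured global radiation of 20 MJ m^-2 (6 h of sunshine) into its diffuse
and direct components.
"""

from datetime import date

from stripshade import DailyWeather, day_context, partition_day

d = date(2021, 7, 20)
ctx = day_context(d.timetuple().tm_yday, latitude_deg=43.267)
print(f"{d} at {ctx.latitude} deg N")
print(f"  declination          {ctx.declination:7.2f} deg")
print(f"  sunrise / sunset     {ctx.sunrise_lst:5.2f} / {ctx.sunset_lst:5.2f} h LST")
print(f"  day length S0        {ctx.max_sunshine_duration:7.2f} h")
print(f"  max elevation        {ctx.max_elevation:7.2f} deg")

weather = DailyWeather(d, global_radiation=20.0, sunshine_duration=6.0)
p = partition_day(weather, ctx)
print(f"  extraterrestrial R0  {p.extraterrestrial:7.2f} MJ m^-2")
print(f"  clearness index      {p.clearness_index:7.3f}")
print(f"  diffuse R_d          {p.diffuse:7.2f} MJ m^-2")
print(f"  direct  R_a          {p.direct:7.2f} MJ m^-2")
print("R_a is the radiation the maize strips can actually block: only the")
print("direct beam casts the well-defined shadows the shading model tracks.")
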