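"""Atmospheric demand: daily reference ET and aridity classification.

Builds a few days of greenhouse climate, computes FAO-56 Penman-Monteith
reference evapotranspiration (ET0) for each, and classifies two
collection sites by their UNEP aridity index.
"""

from phenowater import ClimateDay, aridity_index, et0_from_climate

days = [
    ClimateDay(das=20, t_mean=18.5, t_min=13.9, t_max=23.6, rh_mean=68.0,
               radiation=11.2),
    ClimateDay(das=21, t_mean=21.0, t_min=16.2, t_max=26.1, rh_mean=55.0,
               radiation=17.8),
    ClimateDay(das=22, t_mean=19.2, t_min=14.5, t_max=24.0, rh_mean=74.0,
               radiation=8.9),
]
print("day  ET0 (mm/d)   <- evaporative demand of a reference surface")
for day in days:
    print(f"{day.das:>3}  {et0_from_climate(day):10.2f}")

# annual rainfall vs annual reference ET at two contrasting origins
for site, p, et0 in [("Nile delta", 17.3, 518.1),
                     ("Portuguese coast", 540.4, 523.9)]:
    ai, cls = aridity_index(p, et0)
    print(f"{site}: AI = {ai:.2f} -> {cls}"
          "  (AI = rain/ET0; < 0.05 hyperarid ... >= 0.65 humid)")
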