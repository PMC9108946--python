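"""Score natural-science series: annual rates and 5-point categories.

Builds a decade of fisheries landings and a two-snapshot mangrove extent
record, reduces each to a rate in percent per year, and places it on the
common 5-point trend scale using the packaged sector thresholds.
"""

from ecoconverge import EcosystemSeries, score_series

# landings (tonnes) growing ~2%/yr with one bad year
landings = EcosystemSeries(
    "puerto", "fisheries",
    [(2010, 100), (2011, 103), (2012, 105), (2013, 96), (2014, 104),
     (2015, 107), (2016, 110), (2017, 111), (2018, 115), (2019, 118)],
)
rate, score = score_series(landings, "fisheries")
print(f"fisheries: {rate.rate_pct_per_year:+.2f} %/yr ({rate.method}, "
      f"{rate.n_intervals} intervals) -> score {score.score:+d}")

# mangrove extent (km2) mapped in just two years
mangrove = EcosystemSeries("hoi_an", "mangrove", [(2003, 84.0), (2016, 71.5)])
rate, score = score_series(mangrove, "mangrove")
print(f"mangrove:  {rate.rate_pct_per_year:+.2f} %/yr ({rate.method}) "
      f"-> score {score.score:+d}")

print("\nScores live on the shared 5-point scale: -2 strong decline .. "
      "+2 strong improvement;\nfisheries needs >10 %/yr to leave the "
      "'no or slight change' band, mangrove only >0.1 %/yr.")
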