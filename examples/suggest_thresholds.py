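"""Derive category boundaries from the cross-site spread of rates.

When no literature value pins the sector boundaries, the cross-site
median and standard deviation of the per-site rates calibrate a proposed
(inner, outer) pair. The proposal is a heuristic starting point — it is
flagged as such and never applied silently.
"""

from ecoconverge import suggest_cutoffs
from ecoconverge.ns_scoring import RateSummary

# per-site mean year-on-year changes for a fisheries-like sector
rates = [-16.0, 2.0, 20.0]
summaries = [
    RateSummary(f"site{i}", "fisheries", "present", r, "yoy_mean", 10)
    for i, r in enumerate(rates)
]
out = suggest_cutoffs(summaries)
print(f"rates: {rates}")
print(f"diagnostics: median {out.median:+.1f}, SD {out.sd:.1f}, "
      f"range [{out.minimum:+.1f}, {out.maximum:+.1f}]")
print(f"proposal: inner {out.proposal.inner:g}, outer {out.proposal.outer:g} "
      f"%/yr (provenance: {out.proposal.provenance}, heuristic)")
print("\nWith a cross-site SD of 18 the proposal lands on the (10, 20) "
      "fisheries boundary\npair: rates within +-10 %/yr read as 'no or "
      "slight change', beyond +-20 as strong.")
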