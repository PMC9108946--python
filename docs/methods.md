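# Methods

This note documents the model behind `ecoconverge`, the parameters that
matter, the design choices made where the procedure was genuinely open,
and what the synthetic-data tests do and do not establish.

## The harmonization model

The package compares two evidence strands about decade-scale change in
coastal ecosystem quality by forcing both onto one ordinal 5-point trend
scale, {−2, −1, 0, +1, +2}, anchored "strong decline" to "strong
improvement".

**Natural-science strand.** A record is an annual series of a nonnegative
quantity (landings, biomass, areal extent) for one site × habitat ×
scenario. It is reduced to a signed rate in percent per year:

* *Year-on-year (YoY) pipeline* (default for series with ≥ 3 points):
  gap years are filled by linear interpolation onto the full annual grid
  (never extrapolating past the endpoints), then the per-interval percent
  changes are averaged. Averaging interval changes rather than comparing
  endpoints keeps a single anomalous first or last year of a short series
  from dominating the trend, at the cost of weighting all intervals
  equally. The summary statistic is the mean per series; the median is
  available (`yoy_statistic="median"`) and is also what the cross-site
  diagnostics report.
* *Two-point rate* (default for two-snapshot extent data): the net
  percent change of the initial extent divided by the elapsed years
  ("linear"). A compound (log) rate is available because both conventions
  are used in the deforestation literature; for the small rates at which
  the sector boundaries sit the two agree to first order (property-tested
  to < 0.01 percentage points at total changes < 1%). Linear is the
  default because it reads directly as "percent of the initial extent per
  year".

The rate is categorized by a symmetric boundary pair (inner, outer) per
sector. The middle band is closed and boundary values belong to the
milder category (a fisheries rate of exactly 20 %/yr scores +1, not +2) —
the literal reading of the "> inner to outer" band notation. Packaged
defaults: fisheries (10, 20), mangrove (0.1, 0.5), coral (1, 2), seagrass
(1, 5), all %/yr; mangrove/coral/seagrass from regional literature,
fisheries from the cross-site spread of observed YoY changes. Aquaculture
series are scored with the fisheries boundaries. A zero base value in a
percent change is a hard error rather than a silent skip: a zero
denominator is a data problem the user must resolve.

**Threshold derivation.** Where no literature boundary exists,
`suggest_cutoffs` reports cross-site diagnostics (median, SD, min, max)
and proposes (inner, outer) = (SD/2, SD), each rounded to the nearest 5
with a floor of 1. The rounding constant reflects that these boundaries
are communication categories, not estimates — a cross-site SD of 18 %/yr
yields the (10, 20) fisheries pair. The proposal is explicitly flagged
heuristic and `median_derived`; it is never applied without the user
adopting it, and a degenerate spread (SD ≈ 0, bands indistinguishable)
returns no proposal plus a warning.

**Scenario agreement.** Modelled future series come per climate-forcing
scenario (RCP labels). Each scenario is scored separately; the agreement
flag records whether all land on the same category. On disagreement the
score of the median-rate scenario is used with a warning — a robust
middle choice that avoids privileging any one forcing pathway. Scenario
"present" feeds the *past* cell of the matrix; any other label feeds the
*future* cell.

**Community-perception strand.** Responses arrive on a 5-point (−2..+2)
or 7-point (−3..+3) scale depending on the survey instrument. The
7-point mapping collapses the two mild categories on each side
(−3→−2, {−2,−1}→−1, 0→0, {1,2}→+1, 3→+2); it is monotone, surjective and
sign-preserving. Mapping is applied per response *before* taking the
median, so mixed-scale studies aggregate commensurable values; for odd
sample sizes this equals mapping the median (monotone invariance), and
the two differ only on even-size ties. A non-integer median (even n) is
rounded half away from zero by default, preserving the direction of the
majority signal; half-toward-zero is available, and the raw median is
always retained. No respondent weighting or representativeness
correction is applied; an optional 0/1 `include` column masks respondents
out before aggregation.

**Convergence.** d = NS − CP ∈ [−4, +4]. Band labels depend only on |d|:
0 full convergence, 1 strong convergence, 2 noticeable divergence, ≥ 3
strong divergence. The assignment of |d| = 2 to the divergence side is a
judgment call — the two scores disagree by a full step on a 5-point
scale — and the cutoffs are configurable (`BandCutoffs`). Unpaired keys
(a habitat measured but not surveyed, or vice versa) are preserved as
explicitly missing cells, never dropped.

## Visualization

The heat map is a sites × (habitat, direction) grid. Cell fill comes
from a 9-colour diverging ramp indexed by d + 4; the default is the
ColorBrewer RdBu 9-class palette, whose centre (#f7f7f7) is the lightest
entry. Style validation enforces the invariant that matters — lightness
(CIE L*, computed from sRGB via relative luminance) maximal at d = 0 and
non-increasing toward both ends — rather than any particular palette, so
the ramp is fully overridable. Arrows use five slopes (±60° strong, ±30°
mild, 0° flat; a display convention, mirrored vertically for negative
scores), red for NS and blue for CP by default. Habitat icons (fish,
shellfish, mangrove tree, coral, seagrass blades) are built-in vector
glyphs. SVG output is generated by a deterministic primitive writer — no
timestamps, no generated ids — so identical inputs give identical bytes;
PNG is rasterized from the same primitives at 2× via Pillow. A basic
mode (`show_arrows=False, show_icons=False`) renders colour-only maps.

## Synthetic data

The generator emulates the shapes the pipeline consumes, with planted
ground truth:

* Series: vₜ = vₜ₋₁ · (1 + g/100) · exp(εₜ), εₜ ~ N(0, σ) — multiplicative
  lognormal noise keeps values positive, as landings and extents must be.
  The noise-free YoY mean equals g exactly; under noise the expected YoY
  change is 100·((1 + g/100)·exp(σ²/2) − 1), which the Monte-Carlo test
  verifies. Gap years can be knocked out (not the endpoints).
* Surveys: response = clip(round(true + bias + N(0, δ))) on the declared
  scale; δ = 0 reproduces the true score exactly. The `bias` offset
  (default 0) emulates systematic perception shifts such as
  shifting-baseline optimism, which the model otherwise does not attempt
  to capture.
* Every record draws from its own seed substream (FNV-1a hash of its key
  XORed with the study seed), so output is invariant to spec order and
  byte-identical for a fixed seed.

The default study (`default_config`) is 2 sites × 2 habitats ×
past/future (8 cells) — the smallest layout that exercises both strands,
both directions, the scenario-agreement path, both Likert widths, and
planted d values from full convergence to strong divergence. True trends
sit mid-band (e.g. fisheries +2, −15, −25, +15 %/yr; mangrove −0.3,
−1.0 %/yr). The reference noisy regime uses series volatility σ = 0.05
on fisheries — scaled down for extent habitats in proportion to their
band amplitude, reflecting that satellite-mapped extents vary far less
year-to-year than landings (the same asymmetry the thresholds encode) —
response jitter δ = 1, and n = 252 respondents per cell, the smallest
community sample size the method was demonstrated with. Under these
conditions the regression test requires ≥ 90% of 200 pinned seeds to
recover *every* cell's d; the suite observes ~99%.

What passing these tests shows: the pipeline's arithmetic, boundary
conventions, mapping and plumbing are correct, and the method is robust
to moderate idiosyncratic noise at realistic sample sizes. What they do
not show: robustness to the biases real data carry — shifting baselines,
event-driven perception swings, unrepresentative sampling, effort-driven
landings trends (catch-per-unit-effort normalization is out of scope) —
none of which the symmetric noise model generates.

## Numerical and interface choices

* Percent changes and rates are IEEE doubles throughout; scores are exact
  integers, so no tolerance enters after categorization. Category
  boundaries compare with plain `<`/`<=` — a rate within float error of a
  boundary lands deterministically on one side, which the boundary tests
  pin down.
* CSV dialect: UTF-8, comma-separated, mandatory header, decimal point;
  years are integers. Schema violations name the 1-based CSV row. An
  empty scenario field means "present". Habitat vocabulary is closed:
  {fisheries, aquaculture, mangrove, coral, seagrass}.
* The fixture writer formats series values with 6 decimals; scores,
  medians and d round-trip exactly through the CSV/JSON outputs
  (round-trip tested).
* Logging records every interpolated year, every rounding event and the
  threshold provenance, so a scored table can be audited back to its
  inputs.

## Known limitations

* The YoY mean over a consecutive grid is invariant to the interpolation
  of interior gaps only in aggregate (telescoping); the per-interval
  values it averages are not observations. Long gaps therefore pull the
  rate toward the endpoint trend.
* Even-n Likert ties make the CP score depend on the rounding rule; both
  rules are exposed and the raw median is always reported.
* The divergence scale treats the 5-point categories as equally spaced;
  d is an ordinal difference, not a calibrated effect size, and no
  statistical test of NS–CP agreement is attempted.
* Sites, habitats and directions are compared only where both strands
  exist; the package makes missingness visible but does not impute it.
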