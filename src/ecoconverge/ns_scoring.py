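"""Natural-science (NS) strand: trend rates and 5-point categorization.

An ecosystem record is a short annual series — fisheries landings or
stock-survey biomass, habitat extent for mangrove/coral/seagrass, or
modelled future biomass under a climate scenario. Each series is reduced
to a single signed rate of change in percent per year:

* series with three or more observations: the mean (or median) of the
  year-on-year percent changes, computed on the complete annual grid
  (gap years are linearly interpolated first). Averaging year-on-year
  changes rather than comparing endpoints keeps a single outlier year at
  either end of a short series from dominating the trend.
* two-snapshot extent data (e.g. mangrove area mapped in just two years):
  the net percent change of the initial extent divided by the elapsed
  years ("linear"), or the continuous compound rate ``ln(a2/a1)/dt``
  ("compound"). The two agree to first order for the small rates at which
  the sector thresholds sit.

The rate is then categorized on the common 5-point scale {-2..+2} using
the sector's threshold pair (:mod:`ecoconverge.thresholds`).
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .cp_scoring import HarmonizedScore
from .thresholds import DEFAULT_THRESHOLDS, SectorThresholds, ThresholdTable

logger = logging.getLogger(__name__)

__all__ = [
    "EcosystemSeries",
    "RateSummary",
    "CutoffSuggestion",
    "ScenarioScores",
    "yoy_changes",
    "summarize_yoy",
    "two_point_rate",
    "interpolate_series",
    "categorize_rate",
    "rate_for_series",
    "score_series",
    "suggest_cutoffs",
    "score_scenarios",
]


@dataclass(frozen=True)
class EcosystemSeries:
    """One site x habitat x scenario annual value series.

    ``observations`` is an ordered sequence of ``(year, value)`` pairs with
    strictly increasing integer years and nonnegative values (landings
    mass, biomass, or areal extent). ``scenario`` defaults to ``"present"``;
    any other label marks a modelled future series (e.g. an RCP variant).
    """

    site: str
    habitat: str
    observations: tuple
    scenario: str = "present"

    def __post_init__(self) -> None:
        obs = tuple((int(y), float(v)) for y, v in self.observations)
        object.__setattr__(self, "observations", obs)
        if len(obs) < 2:
            raise ValueError(
                f"series {self.key} needs at least 2 observations, got {len(obs)}"
            )
        years = [y for y, _ in obs]
        if any(y2 <= y1 for y1, y2 in zip(years, years[1:])):
            raise ValueError(
                f"series {self.key} years must be strictly increasing, got {years}"
            )
        negative = [(y, v) for y, v in obs if v < 0]
        if negative:
            raise ValueError(
                f"series {self.key} has negative values at {negative}"
            )

    @property
    def key(self) -> tuple:
        return (self.site, self.habitat, self.scenario)

    @property
    def years(self) -> list:
        return [y for y, _ in self.observations]

    @property
    def values(self) -> list:
        return [v for _, v in self.observations]

    @property
    def is_annual_grid(self) -> bool:
        years = self.years
        return years[-1] - years[0] == len(years) - 1


@dataclass(frozen=True)
class RateSummary:
    """A series reduced to a signed rate in percent per year."""

    site: str
    habitat: str
    scenario: str
    rate_pct_per_year: float
    method: str  # yoy_mean | yoy_median | two_point_linear | two_point_compound
    n_intervals: int

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if not math.isfinite(self.rate_pct_per_year):
            raise ValueError(
                f"rate for {self.site}/{self.habitat}/{self.scenario} is not finite"
            )


def yoy_changes(series: EcosystemSeries) -> list:
    """Year-on-year percent changes, one per consecutive year pair.

    Element ``t`` is ``(value_t - value_{t-1}) / value_{t-1} * 100``. The
    series must sit on a complete annual grid — run
    :func:`interpolate_series` first if it has gap years. A zero value
    anywhere except the final year is a division hazard and raises with
    the offending year named.
    """
    if not series.is_annual_grid:
        raise ValueError(
            f"series {series.key} has gap years {sorted(set(range(series.years[0], series.years[-1] + 1)) - set(series.years))}; "
            f"apply interpolate_series before computing year-on-year changes"
        )
    changes = []
    obs = series.observations
    for (y1, v1), (_, v2) in zip(obs, obs[1:]):
        if v1 <= 0:
            raise ZeroDivisionError(
                f"series {series.key}: value {v1} in year {y1} cannot serve "
                f"as the base of a percent change"
            )
        changes.append((v2 - v1) / v1 * 100.0)
    return changes


def summarize_yoy(changes: Sequence[float], method: str = "mean") -> float:
    """Collapse year-on-year changes to one percentage (mean or median)."""
    changes = list(changes)
    if not changes:
        raise ValueError("cannot summarize an empty sequence of changes")
    if method == "mean":
        return float(statistics.fmean(changes))
    if method == "median":
        return float(statistics.median(changes))
    raise ValueError(f"method must be 'mean' or 'median', got {method!r}")


def two_point_rate(
    a1: float, a2: float, y1: int, y2: int, method: str = "linear"
) -> float:
    """Annual percent rate of change between two extent snapshots.

    ``linear`` (default): ``((a2 - a1) / a1) / (y2 - y1) * 100`` — the net
    percent change of the initial extent spread evenly over the elapsed
    years. ``compound``: ``ln(a2 / a1) / (y2 - y1) * 100`` — the
    continuous growth rate. The two coincide to first order for small
    total changes.
    """
    if y2 <= y1:
        raise ValueError(f"need y2 > y1, got y1={y1}, y2={y2}")
    if a1 <= 0:
        raise ZeroDivisionError(
            f"initial extent {a1} in year {y1} cannot serve as a percent base"
        )
    dt = y2 - y1
    if method == "linear":
        return (a2 - a1) / a1 / dt * 100.0
    if method == "compound":
        if a2 <= 0:
            raise ValueError(
                f"extent {a2} in year {y2} admits no compound (log) rate"
            )
        return math.log(a2 / a1) / dt * 100.0
    raise ValueError(f"method must be 'linear' or 'compound', got {method!r}")


def interpolate_series(series: EcosystemSeries) -> EcosystemSeries:
    """Fill gap years by linear interpolation onto the full annual grid.

    Observed values are untouched and nothing is extrapolated beyond the
    first or last observed year; the operation is idempotent. Interpolated
    years are logged.
    """
    if series.is_annual_grid:
        return series
    years = np.array(series.years)
    values = np.array(series.values)
    grid = np.arange(years[0], years[-1] + 1)
    filled = np.interp(grid, years, values)
    gap_years = sorted(set(grid.tolist()) - set(years.tolist()))
    logger.info(
        "interpolated gap years %s for series %s", gap_years, series.key
    )
    return EcosystemSeries(
        site=series.site,
        habitat=series.habitat,
        scenario=series.scenario,
        observations=tuple(zip(grid.tolist(), filled.tolist())),
    )


def categorize_rate(
    rate: float,
    sector: str,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
) -> int:
    """Place a rate (% per year) on the 5-point scale for its sector.

    The middle band is closed and boundary values belong to the milder
    category: with fisheries boundaries (10, 20), a rate of exactly 20
    scores +1 and exactly 10 scores 0.
    """
    if not math.isfinite(rate):
        raise ValueError(f"rate must be finite, got {rate}")
    t = thresholds[sector]
    if rate > t.outer:
        return 2
    if rate > t.inner:
        return 1
    if rate >= -t.inner:
        return 0
    if rate >= -t.outer:
        return -1
    return -2


def rate_for_series(
    series: EcosystemSeries,
    rate_method: str = "auto",
    yoy_statistic: str = "mean",
) -> RateSummary:
    """Reduce a series to its annual rate, picking the method by shape.

    ``rate_method="auto"`` uses the two-point linear rate for two-snapshot
    series and the year-on-year pipeline (interpolate, then average the
    annual percent changes) otherwise. Explicit choices: ``"yoy"``,
    ``"linear"``, ``"compound"``.
    """
    obs = series.observations
    if rate_method == "auto":
        rate_method = "linear" if len(obs) == 2 else "yoy"
    if rate_method == "yoy":
        full = interpolate_series(series)
        rate = summarize_yoy(yoy_changes(full), yoy_statistic)
        return RateSummary(
            site=series.site,
            habitat=series.habitat,
            scenario=series.scenario,
            rate_pct_per_year=rate,
            method=f"yoy_{yoy_statistic}",
            n_intervals=len(full.observations) - 1,
        )
    if rate_method in ("linear", "compound"):
        (y1, a1), (y2, a2) = obs[0], obs[-1]
        rate = two_point_rate(a1, a2, y1, y2, rate_method)
        return RateSummary(
            site=series.site,
            habitat=series.habitat,
            scenario=series.scenario,
            rate_pct_per_year=rate,
            method=f"two_point_{rate_method}",
            n_intervals=1,
        )
    raise ValueError(
        f"rate_method must be 'auto', 'yoy', 'linear' or 'compound', "
        f"got {rate_method!r}"
    )


def score_series(
    series: EcosystemSeries,
    sector: str,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    direction: str = "past",
    rate_method: str = "auto",
    yoy_statistic: str = "mean",
) -> tuple:
    """Convenience: series -> (RateSummary, HarmonizedScore) in one step."""
    summary = rate_for_series(series, rate_method, yoy_statistic)
    score = categorize_rate(summary.rate_pct_per_year, sector, thresholds)
    harmonized = HarmonizedScore(
        source="NS",
        site=series.site,
        habitat=series.habitat,
        direction=direction,
        score=score,
        n=summary.n_intervals,
    )
    return summary, harmonized


@dataclass(frozen=True)
class CutoffSuggestion:
    """Cross-site diagnostics plus a heuristic threshold proposal.

    The proposal ``(SD/2, SD)``, each rounded to the nearest 5 with a
    floor of 1, reproduces the fisheries calibration in which a cross-site
    standard deviation of 18 yields the (10, 20) boundary pair. It is a
    heuristic starting point and is never applied without the user
    adopting it explicitly; ``proposal`` is ``None`` when the dispersion
    is too degenerate to separate the bands.
    """

    median: float
    sd: float
    minimum: float
    maximum: float
    n: int
    proposal: Optional[SectorThresholds]
    warnings: tuple = ()
    heuristic: bool = True


def _round_to_5(x: float) -> float:
    return max(1.0, round(x / 5.0) * 5.0)


def suggest_cutoffs(site_rates: Sequence[RateSummary]) -> CutoffSuggestion:
    """Propose sector thresholds from the cross-site spread of rates.

    Used when no literature boundary exists for a sector: the cross-site
    median locates the central band and the standard deviation scales the
    proposed ``(inner, outer) = (SD/2, SD)`` pair (rounded to the nearest
    5, floor 1, symmetric about zero). Always returns the diagnostics
    (median, SD, min, max); the proposal is flagged ``median_derived``.
    """
    rates = [r.rate_pct_per_year for r in site_rates]
    if len(rates) < 2:
        raise ValueError(
            f"need at least 2 site rates to suggest cut-offs, got {len(rates)}"
        )
    sd = float(statistics.stdev(rates))
    diagnostics = dict(
        median=float(statistics.median(rates)),
        sd=sd,
        minimum=min(rates),
        maximum=max(rates),
        n=len(rates),
    )
    warnings_: list = []
    inner, outer = _round_to_5(sd / 2.0), _round_to_5(sd)
    if sd == 0.0 or inner >= outer:
        warnings_.append(
            f"degenerate dispersion (SD={sd:g}): proposed pair "
            f"({inner:g}, {outer:g}) cannot separate five bands; "
            f"choose thresholds from the literature instead"
        )
        proposal = None
    else:
        proposal = SectorThresholds(inner, outer, "median_derived")
    return CutoffSuggestion(
        **diagnostics, proposal=proposal, warnings=tuple(warnings_)
    )


@dataclass(frozen=True)
class ScenarioScores:
    """Per-scenario rates and scores, with an agreement flag.

    ``agreement`` is true iff every scenario lands on the same 5-point
    score (vacuously true for a single scenario); ``consensus_score`` is
    that common score, or on disagreement the score of the scenario with
    the median rate.
    """

    rates: Mapping[str, RateSummary]
    scores: Mapping[str, int]
    agreement: bool
    consensus_score: int


def score_scenarios(
    series_by_scenario: Mapping[str, EcosystemSeries],
    sector: str,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    rate_method: str = "auto",
    yoy_statistic: str = "mean",
) -> ScenarioScores:
    """Score each scenario of one site x habitat and compare the outcomes.

    Mirrors the climate-scenario robustness check: modelled future series
    under alternative forcing pathways should land on the same 5-point
    score; the flag records whether they do.
    """
    if not series_by_scenario:
        raise ValueError("need at least one scenario")
    rates = {}
    scores = {}
    for name in sorted(series_by_scenario):
        summary = rate_for_series(series_by_scenario[name], rate_method, yoy_statistic)
        rates[name] = summary
        scores[name] = categorize_rate(summary.rate_pct_per_year, sector, thresholds)
    unique = set(scores.values())
    agreement = len(unique) == 1
    if agreement:
        consensus = unique.pop()
    else:
        by_rate = sorted(rates, key=lambda k: rates[k].rate_pct_per_year)
        median_scenario = by_rate[(len(by_rate) - 1) // 2]
        consensus = scores[median_scenario]
        logger.warning(
            "scenario scores disagree (%s); using score %d of median-rate "
            "scenario %r", scores, consensus, median_scenario,
        )
    return ScenarioScores(
        rates=rates, scores=scores, agreement=agreement, consensus_score=consensus
    )
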