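"""Synthetic study generator with known ground truth.

Emulates the two data shapes the scoring pipeline consumes:

* short annual ecosystem series (2-20 points, optionally with gap years
  or reduced to two extent snapshots), generated as a multiplicative
  process ``value_t = value_{t-1} * (1 + trend/100) * exp(eps_t)`` with
  ``eps_t ~ Normal(0, noise_sd)`` — lognormal noise keeps landings and
  areal extents positive by construction;
* integer Likert samples on a 5- or 7-point scale, generated as the true
  central score plus symmetric discrete jitter (a rounded normal with SD
  ~ ``dispersion``), clamped to the scale range. An optional constant
  ``bias`` shifts responses before clamping, emulating systematic
  perception offsets (e.g. shifting-baseline optimism); it defaults to 0.

Because the true trend and the true central score are known, end-to-end
recovery of (ns_score, cp_score, d) can be tested without any external
data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cp_scoring import SurveySample
from .ns_scoring import EcosystemSeries, categorize_rate
from .thresholds import DEFAULT_THRESHOLDS, ThresholdTable, save_thresholds

__all__ = [
    "SeriesSpec",
    "SurveySpec",
    "SimulationConfig",
    "simulate_timeseries",
    "simulate_survey",
    "build_study",
    "make_fixture_study",
    "default_config",
]


@dataclass(frozen=True)
class SeriesSpec:
    """Ground truth for one synthetic ecosystem series."""

    site: str
    habitat: str
    trend_pct: float
    noise_sd: float = 0.0
    scenario: str = "present"
    start_year: int = 2010
    n_years: int = 11
    gaps: tuple = ()
    start_value: float = 100.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_years < 2:
            raise ValueError("a series spans at least 2 years")
        if self.trend_pct <= -100:
            raise ValueError("trend_pct must exceed -100 (values stay positive)")


@dataclass(frozen=True)
class SurveySpec:
    """Ground truth for one synthetic Likert sample."""

    site: str
    habitat: str
    direction: str
    true_score: int
    dispersion: float = 0.0
    scale_points: int = 5
    n: int = 100
    bias: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        radius = 2 if self.scale_points == 5 else 3
        if not -radius <= self.true_score <= radius:
            raise ValueError(
                f"true_score {self.true_score} outside the "
                f"{self.scale_points}-point range"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """A full synthetic mini-study: series specs + survey specs + seed."""

    series: tuple
    surveys: tuple
    seed: int = 0
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS


def simulate_timeseries(
    trend_pct: float,
    noise_sd: float,
    years: Sequence[int],
    gaps: Sequence[int] = (),
    seed: int | np.random.Generator = 0,
    *,
    site: str = "site",
    habitat: str = "fisheries",
    scenario: str = "present",
    start_value: float = 100.0,
) -> EcosystemSeries:
    """Generate one annual series with multiplicative lognormal noise.

    ``years`` is the full annual span; years listed in ``gaps`` are
    removed after generation (they may not include the endpoints, which
    would silently shorten the span). Identical seeds give identical
    series.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    years = list(years)
    if len(years) < 2:
        raise ValueError("need at least 2 years")
    gapset = set(gaps)
    if years[0] in gapset or years[-1] in gapset:
        raise ValueError("gap years may not include the series endpoints")
    eps = rng.normal(0.0, noise_sd, size=len(years) - 1) if noise_sd > 0 else np.zeros(len(years) - 1)
    values = [float(start_value)]
    for e in eps:
        values.append(values[-1] * (1.0 + trend_pct / 100.0) * float(np.exp(e)))
    obs = [(y, v) for y, v in zip(years, values) if y not in gapset]
    return EcosystemSeries(
        site=site, habitat=habitat, scenario=scenario, observations=tuple(obs)
    )


def simulate_survey(
    true_score: int,
    dispersion: float,
    n: int,
    scale_points: int = 5,
    seed: int | np.random.Generator = 0,
    *,
    site: str = "site",
    habitat: str = "fisheries",
    direction: str = "past",
    bias: float = 0.0,
) -> SurveySample:
    """Generate one Likert sample around a true central score.

    Responses are ``true_score + bias + round(Normal(0, dispersion))``
    clamped to the declared scale range; ``dispersion=0`` yields a
    constant sample. Identical seeds give identical samples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    radius = 2 if scale_points == 5 else 3
    if dispersion > 0:
        jitter = np.rint(rng.normal(0.0, dispersion, size=n))
    else:
        jitter = np.zeros(n)
    responses = np.clip(np.rint(true_score + bias + jitter), -radius, radius)
    return SurveySample(
        site=site,
        habitat=habitat,
        direction=direction,
        scale_points=scale_points,
        responses=tuple(int(v) for v in responses),
    )


def _spec_seed(base: int, tag: str) -> int:
    # stable per-record substream (FNV-1a), independent of spec order
    h = 2166136261
    for ch in tag.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return (int(base) ^ h) & 0x7FFFFFFF


def build_study(config: SimulationConfig) -> tuple:
    """Generate all series and samples of a study, plus the ground truth.

    Returns ``(series_list, sample_list, truth_frame)`` where the truth
    frame holds the intended ns_score / cp_score / d per (site, habitat,
    direction) cell, derived from the noise-free trend and the true
    central score. Every record draws from its own seed substream, so the
    output is invariant to spec order.
    """
    series_list = []
    for sp in config.series:
        years = range(sp.start_year, sp.start_year + sp.n_years)
        s = simulate_timeseries(
            sp.trend_pct, sp.noise_sd, years, sp.gaps,
            _spec_seed(config.seed, f"ns|{sp.site}|{sp.habitat}|{sp.scenario}"),
            site=sp.site, habitat=sp.habitat, scenario=sp.scenario,
            start_value=sp.start_value,
        )
        series_list.append(s)
    sample_list = []
    for sv in config.surveys:
        sample_list.append(
            simulate_survey(
                sv.true_score, sv.dispersion, sv.n, sv.scale_points,
                _spec_seed(config.seed, f"cp|{sv.site}|{sv.habitat}|{sv.direction}"),
                site=sv.site, habitat=sv.habitat, direction=sv.direction,
                bias=sv.bias,
            )
        )
    truth = _ground_truth(config)
    return series_list, sample_list, truth


def _true_cp_score(spec: SurveySpec) -> int:
    from .cp_scoring import LIKERT7_TO_5

    if spec.scale_points == 7:
        return LIKERT7_TO_5[spec.true_score]
    return spec.true_score


def _ground_truth(config: SimulationConfig) -> pd.DataFrame:
    from .io import sector_for_habitat

    ns_truth = {}
    for sp in config.series:
        direction = "past" if sp.scenario == "present" else "future"
        key = (sp.site, sp.habitat, direction)
        score = categorize_rate(
            sp.trend_pct, sector_for_habitat(sp.habitat), config.thresholds
        )
        ns_truth.setdefault(key, score)
    cp_truth = {
        (sv.site, sv.habitat, sv.direction): _true_cp_score(sv)
        for sv in config.surveys
    }
    rows = []
    for key in dict.fromkeys(list(ns_truth) + list(cp_truth)):
        ns = ns_truth.get(key)
        cp = cp_truth.get(key)
        rows.append(
            {
                "site": key[0], "habitat": key[1], "direction": key[2],
                "true_ns_score": ns, "true_cp_score": cp,
                "true_d": None if ns is None or cp is None else ns - cp,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["site", "habitat", "direction",
                 "true_ns_score", "true_cp_score", "true_d"],
    )


def make_fixture_study(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write a self-consistent mini-study to ``outdir``.

    Emits ``ns.csv`` (site,habitat,scenario,year,value), ``cp.csv``
    (site,habitat,direction,scale_points,response), ``thresholds.yaml``
    and ``ground_truth.csv``. Output is byte-identical for a fixed seed.
    Returns the paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series_list, sample_list, truth = build_study(config)

    ns_rows = [
        {"site": s.site, "habitat": s.habitat, "scenario": s.scenario,
         "year": y, "value": f"{v:.6f}"}
        for s in series_list for y, v in s.observations
    ]
    ns_path = outdir / "ns.csv"
    pd.DataFrame(ns_rows, columns=["site", "habitat", "scenario", "year", "value"]).to_csv(
        ns_path, index=False
    )

    cp_rows = [
        {"site": s.site, "habitat": s.habitat, "direction": s.direction,
         "scale_points": s.scale_points, "response": r}
        for s in sample_list for r in s.responses
    ]
    cp_path = outdir / "cp.csv"
    pd.DataFrame(
        cp_rows, columns=["site", "habitat", "direction", "scale_points", "response"]
    ).to_csv(cp_path, index=False)

    thr_path = outdir / "thresholds.yaml"
    save_thresholds(config.thresholds, thr_path)
    truth_path = outdir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    return {
        "ns": ns_path, "cp": cp_path,
        "thresholds": thr_path, "ground_truth": truth_path,
    }


def default_config(
    seed: int = 0, noise_sd: float = 0.0, dispersion: float = 0.0, n: int = 252
) -> SimulationConfig:
    """A 2-site x 2-habitat x past/future study with known scores.

    True trends sit well inside their category bands (fisheries +-2 to
    +-25 %/yr, mangrove -0.3 to -1 %/yr) and true perception scores span
    the scale, so the intended d values cover convergence and divergence
    cases. ``noise_sd`` is the log-scale volatility of the *fisheries*
    series; extent habitats get it scaled down in proportion to their
    band amplitude, mirroring how areal-extent series vary far less from
    year to year than landings do (the same asymmetry the sector
    thresholds encode). ``n`` defaults to 252 respondents per cell, the
    size of the smallest community sample the method was demonstrated on.
    """
    # volatility relative to fisheries, proportional to the outer threshold
    vol = {"fisheries": 1.0, "mangrove": 0.5 / 20, "coral": 2 / 20, "seagrass": 5 / 20}

    def _noise(habitat: str) -> float:
        return noise_sd * vol[habitat]

    series = (
        SeriesSpec("siteA", "fisheries", trend_pct=2.0, noise_sd=_noise("fisheries")),
        SeriesSpec("siteA", "fisheries", trend_pct=-15.0, noise_sd=_noise("fisheries"),
                   scenario="rcp45"),
        SeriesSpec("siteA", "mangrove", trend_pct=-0.3, noise_sd=_noise("mangrove")),
        SeriesSpec("siteA", "mangrove", trend_pct=-1.0, noise_sd=_noise("mangrove"),
                   scenario="rcp45"),
        SeriesSpec("siteB", "fisheries", trend_pct=-25.0, noise_sd=_noise("fisheries")),
        SeriesSpec("siteB", "fisheries", trend_pct=15.0, noise_sd=_noise("fisheries"),
                   scenario="rcp45"),
        SeriesSpec("siteB", "coral", trend_pct=1.5, noise_sd=_noise("coral")),
        SeriesSpec("siteB", "coral", trend_pct=-3.0, noise_sd=_noise("coral"),
                   scenario="rcp45"),
    )
    surveys = (
        SurveySpec("siteA", "fisheries", "past", true_score=0,
                   dispersion=dispersion, scale_points=5, n=n),
        SurveySpec("siteA", "fisheries", "future", true_score=-1,
                   dispersion=dispersion, scale_points=7, n=n),
        SurveySpec("siteA", "mangrove", "past", true_score=2,
                   dispersion=dispersion, scale_points=5, n=n),
        SurveySpec("siteA", "mangrove", "future", true_score=1,
                   dispersion=dispersion, scale_points=7, n=n),
        SurveySpec("siteB", "fisheries", "past", true_score=-2,
                   dispersion=dispersion, scale_points=7, n=n),
        SurveySpec("siteB", "fisheries", "future", true_score=1,
                   dispersion=dispersion, scale_points=5, n=n),
        SurveySpec("siteB", "coral", "past", true_score=1,
                   dispersion=dispersion, scale_points=5, n=n),
        SurveySpec("siteB", "coral", "future", true_score=-3,
                   dispersion=dispersion, scale_points=7, n=n),
    )
    return SimulationConfig(series=series, surveys=surveys, seed=seed)
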