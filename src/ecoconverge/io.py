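"""CSV/YAML interfaces and the end-to-end pipeline.

File formats (UTF-8, comma-separated, header mandatory, decimal point):

* NS input  ``site,habitat,scenario,year,value`` — one row per annual
  observation; empty scenario means "present".
* CP input  ``site,habitat,direction,scale_points,response`` with
  optional ``respondent_id`` and ``include`` (0/1 mask) columns.
* NS output ``site,habitat,scenario,rate_pct_per_year,method,score``.
* CP output ``site,habitat,direction,n,raw_median,score``.
* Convergence output: long CSV + JSON report (see
  :mod:`ecoconverge.convergence`).

``run_pipeline`` chains the four stages: NS scoring -> CP scoring ->
convergence matrix -> heat map, writing every intermediate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .convergence import (
    BandCutoffs,
    ConvergenceMatrix,
    build_matrix,
    write_matrix_csv,
    write_matrix_json,
)
from .cp_scoring import DIRECTIONS, HarmonizedScore, SurveySample, cp_trend_score
from .heatmap import DEFAULT_STYLE, HeatmapStyle, render_heatmap
from .ns_scoring import EcosystemSeries, score_scenarios
from .thresholds import ThresholdTable, load_thresholds

logger = logging.getLogger(__name__)

__all__ = [
    "HABITATS",
    "sector_for_habitat",
    "read_ns_csv",
    "read_cp_csv",
    "score_ns_frame",
    "score_cp_frame",
    "write_ns_scores",
    "write_cp_scores",
    "load_style",
    "RunConfig",
    "run_pipeline",
]

#: Closed habitat vocabulary. Aquaculture (shellfish productivity) is
#: scored with the fisheries method and thresholds.
HABITATS = ("fisheries", "aquaculture", "mangrove", "coral", "seagrass")


def sector_for_habitat(habitat: str) -> str:
    """Threshold sector for a habitat tag (aquaculture -> fisheries)."""
    if habitat not in HABITATS:
        raise ValueError(
            f"unknown habitat {habitat!r}; expected one of {HABITATS}"
        )
    return "fisheries" if habitat == "aquaculture" else habitat


def _read_csv(path: str | Path, required: tuple) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ValueError(f"cannot parse CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; header must "
            f"contain {list(required)}"
        )
    return frame


def read_ns_csv(path: str | Path) -> list:
    """Read ecosystem series records; returns a list of EcosystemSeries.

    Rows are grouped by (site, habitat, scenario); schema violations are
    reported with the offending CSV row number (header = row 1).
    """
    frame = _read_csv(path, ("site", "habitat", "scenario", "year", "value"))
    records = {}
    for idx, row in frame.iterrows():
        rownum = idx + 2  # 1-based, after the header
        site, habitat = row["site"].strip(), row["habitat"].strip()
        scenario = row["scenario"].strip() or "present"
        if habitat not in HABITATS:
            raise ValueError(
                f"{path} row {rownum}: unknown habitat {habitat!r} "
                f"(expected one of {HABITATS})"
            )
        try:
            year = int(row["year"])
            value = float(row["value"])
        except ValueError:
            raise ValueError(
                f"{path} row {rownum}: year must be an integer and value "
                f"a number, got year={row['year']!r} value={row['value']!r}"
            ) from None
        key = (site, habitat, scenario)
        records.setdefault(key, []).append((year, value, rownum))

    series = []
    for (site, habitat, scenario), obs in records.items():
        years = [y for y, _, _ in obs]
        dupes = {y for y in years if years.count(y) > 1}
        if dupes:
            rows = [r for y, _, r in obs if y in dupes]
            raise ValueError(
                f"{path}: duplicate year(s) {sorted(dupes)} for "
                f"{site}/{habitat}/{scenario} (rows {rows})"
            )
        obs_sorted = sorted((y, v) for y, v, _ in obs)
        try:
            series.append(
                EcosystemSeries(
                    site=site, habitat=habitat, scenario=scenario,
                    observations=tuple(obs_sorted),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return series


def read_cp_csv(path: str | Path) -> list:
    """Read survey responses; returns a list of SurveySample.

    Rows are grouped by (site, habitat, direction); an ``include`` column
    (0/1), when present, masks respondents out before aggregation. A
    group must declare a single consistent scale width.
    """
    frame = _read_csv(path, ("site", "habitat", "direction", "scale_points", "response"))
    groups = {}
    for idx, row in frame.iterrows():
        rownum = idx + 2
        site, habitat = row["site"].strip(), row["habitat"].strip()
        direction = row["direction"].strip()
        if habitat not in HABITATS:
            raise ValueError(
                f"{path} row {rownum}: unknown habitat {habitat!r} "
                f"(expected one of {HABITATS})"
            )
        if direction not in DIRECTIONS:
            raise ValueError(
                f"{path} row {rownum}: direction must be 'past' or "
                f"'future', got {direction!r}"
            )
        try:
            scale_points = int(row["scale_points"])
            response = int(row["response"])
        except ValueError:
            raise ValueError(
                f"{path} row {rownum}: scale_points and response must be "
                f"integers, got {row['scale_points']!r}, {row['response']!r}"
            ) from None
        if "include" in frame.columns:
            inc = row["include"].strip()
            if inc not in ("", "0", "1"):
                raise ValueError(
                    f"{path} row {rownum}: include must be 0 or 1, got {inc!r}"
                )
            if inc == "0":
                continue
        key = (site, habitat, direction)
        groups.setdefault(key, []).append((scale_points, response, rownum))

    samples = []
    for (site, habitat, direction), rows in groups.items():
        widths = {w for w, _, _ in rows}
        if len(widths) > 1:
            raise ValueError(
                f"{path}: mixed scale_points {sorted(widths)} for "
                f"{site}/{habitat}/{direction}"
            )
        (width,) = widths
        radius = 2 if width == 5 else 3
        bad = [r for w, v, r in rows if not -radius <= v <= radius]
        if bad:
            raise ValueError(
                f"{path}: responses outside the {width}-point range "
                f"[-{radius}, {radius}] at rows {bad} for "
                f"{site}/{habitat}/{direction}"
            )
        try:
            samples.append(
                SurveySample(
                    site=site, habitat=habitat, direction=direction,
                    scale_points=width,
                    responses=tuple(v for _, v, _ in rows),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return samples


def score_ns_frame(
    series: list,
    thresholds: ThresholdTable,
    rate_method: str = "auto",
    yoy_statistic: str = "mean",
) -> tuple:
    """Score all NS series; returns (rates DataFrame, HarmonizedScores).

    Series of one site x habitat are grouped by scenario: the "present"
    scenario feeds the *past* cell; all other scenarios (modelled futures)
    are scored jointly and feed the *future* cell via the scenario-
    agreement check. Disagreeing future scenarios produce a warning and
    the median-rate scenario's score.
    """
    by_cell = {}
    for s in series:
        direction = "past" if s.scenario == "present" else "future"
        by_cell.setdefault((s.site, s.habitat, direction), {})[s.scenario] = s

    rows = []
    scores = []
    for (site, habitat, direction), by_scenario in by_cell.items():
        result = score_scenarios(
            by_scenario, sector_for_habitat(habitat), thresholds,
            rate_method, yoy_statistic,
        )
        if not result.agreement:
            logger.warning(
                "future scenarios disagree for %s/%s: %s",
                site, habitat, result.scores,
            )
        for name in sorted(result.rates):
            r = result.rates[name]
            rows.append(
                {
                    "site": site, "habitat": habitat, "scenario": name,
                    "rate_pct_per_year": r.rate_pct_per_year,
                    "method": r.method, "score": result.scores[name],
                }
            )
        scores.append(
            HarmonizedScore(
                source="NS", site=site, habitat=habitat, direction=direction,
                score=result.consensus_score,
                n=max(r.n_intervals for r in result.rates.values()),
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=["site", "habitat", "scenario", "rate_pct_per_year", "method", "score"],
    )
    return frame, scores


def score_cp_frame(samples: list, rounding: str = "half-away") -> tuple:
    """Score all CP samples; returns (DataFrame, HarmonizedScores)."""
    scores = [cp_trend_score(s, rounding) for s in samples]
    frame = pd.DataFrame(
        [
            {
                "site": sc.site, "habitat": sc.habitat, "direction": sc.direction,
                "n": sc.n, "raw_median": sc.raw_median, "score": sc.score,
            }
            for sc in scores
        ],
        columns=["site", "habitat", "direction", "n", "raw_median", "score"],
    )
    return frame, scores


def write_ns_scores(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def write_cp_scores(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def load_style(path: str | Path | None = None) -> HeatmapStyle:
    """Load a heat-map style from YAML/JSON, or return the defaults."""
    if path is None:
        return DEFAULT_STYLE
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValueError(f"style file {path} must contain a mapping")
    kwargs = {}
    for key in (
        "ramp", "ns_color", "cp_color", "icons", "missing_fill",
        "output_format", "cell_size", "show_arrows", "show_icons", "show_legend",
    ):
        if key in raw:
            kwargs[key] = tuple(raw[key]) if key == "ramp" else raw[key]
    unknown = set(raw) - set(kwargs)
    if unknown:
        raise ValueError(f"style file {path}: unknown key(s) {sorted(unknown)}")
    return HeatmapStyle(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for the full pipeline run."""

    ns_csv: Path
    cp_csv: Path
    outdir: Path
    thresholds_path: Optional[Path] = None
    style_path: Optional[Path] = None
    rate_method: str = "auto"
    yoy_statistic: str = "mean"
    rounding: str = "half-away"
    band_cutoffs: BandCutoffs = field(default_factory=BandCutoffs)
    image_format: str = "svg"


def run_pipeline(cfg: RunConfig) -> ConvergenceMatrix:
    """NS scoring -> CP scoring -> convergence -> heat map.

    Writes ``ns_scores.csv``, ``cp_scores.csv``, ``convergence.csv``,
    ``convergence.json`` and ``heatmap.svg``/``.png`` into ``cfg.outdir``.
    Missing pairings produce warnings and blank cells, never failures;
    schema violations raise with the CSV row named.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = load_thresholds(cfg.thresholds_path)
    for name, t in thresholds.to_dict().items():
        logger.info(
            "thresholds %s: inner=%g outer=%g (%s)",
            name, t["inner"], t["outer"], t["provenance"],
        )

    series = read_ns_csv(cfg.ns_csv)
    samples = read_cp_csv(cfg.cp_csv)

    ns_frame, ns_scores = score_ns_frame(
        series, thresholds, cfg.rate_method, cfg.yoy_statistic
    )
    cp_frame, cp_scores = score_cp_frame(samples, cfg.rounding)
    write_ns_scores(ns_frame, outdir / "ns_scores.csv")
    write_cp_scores(cp_frame, outdir / "cp_scores.csv")

    matrix = build_matrix(ns_scores, cp_scores, cfg.band_cutoffs)
    n_missing = sum(1 for c in matrix.cells if c.missing)
    if n_missing:
        logger.warning(
            "%d of %d cells lack an NS or CP partner and will render blank",
            n_missing, len(matrix.cells),
        )
    write_matrix_csv(matrix, outdir / "convergence.csv")
    write_matrix_json(matrix, outdir / "convergence.json")

    style = load_style(cfg.style_path)
    if cfg.image_format != style.output_format:
        style = HeatmapStyle(
            **{**style.__dict__, "output_format": cfg.image_format}
        )
    if matrix.cells:
        render_heatmap(matrix, style, outdir / f"heatmap.{style.output_format}")
    else:
        logger.warning("no cells to render; heat map skipped")
    return matrix
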