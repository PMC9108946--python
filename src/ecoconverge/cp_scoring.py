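"""Community-perception (CP) strand: Likert harmonization and trend scoring.

Survey respondents rate perceived 10-year change of a habitat ("much
worse" .. "much better") on either a 5-point (-2..+2) or a 7-point
(-3..+3) integer scale. Both are brought onto the common 5-point scale —
the 7-point responses through a fixed monotone mapping — and a sample is
reduced to a single comparison score by taking the median.

The mapping pairs the published scale anchors:

    7-point:  -3   -2   -1    0    +1   +2   +3
    5-point:  -2   -1   -1    0    +1   +1   +2

Mapping is applied per response *before* the median so that mixed-scale
studies aggregate commensurable values; for odd sample sizes this is
equivalent to mapping the median (monotone invariance), and the two differ
only on even-size ties.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "SurveySample",
    "HarmonizedScore",
    "LIKERT7_TO_5",
    "map_likert7_to5",
    "harmonize_sample",
    "round_half_away",
    "round_half_toward_zero",
    "cp_trend_score",
]

DIRECTIONS = ("past", "future")

#: Fixed 7-point -> 5-point pairing (see module docstring).
LIKERT7_TO_5 = {-3: -2, -2: -1, -1: -1, 0: 0, 1: 1, 2: 1, 3: 2}


@dataclass(frozen=True)
class SurveySample:
    """Likert responses for one site x habitat x time-direction.

    Parameters
    ----------
    site, habitat
        Identifiers matching the natural-science records.
    direction
        ``"past"`` (change over the last decade) or ``"future"``
        (expected change over the next decade).
    scale_points
        5 or 7; every response must lie within the declared range.
    responses
        Integer ratings; ``-scale_radius .. +scale_radius``.
    n_total_surveyed
        Optional number of people approached (responses may be fewer).
    """

    site: str
    habitat: str
    direction: str
    scale_points: int
    responses: tuple
    n_total_surveyed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if self.scale_points not in (5, 7):
            raise ValueError(
                f"scale_points must be 5 or 7, got {self.scale_points}"
            )
        object.__setattr__(self, "responses", tuple(int(v) for v in self.responses))
        radius = self.scale_radius
        bad = [
            i for i, v in enumerate(self.responses) if not (-radius <= v <= radius)
        ]
        if bad:
            raise ValueError(
                f"responses at indices {bad} outside the declared "
                f"{self.scale_points}-point range [-{radius}, {radius}]"
            )

    @property
    def scale_radius(self) -> int:
        return 2 if self.scale_points == 5 else 3

    @property
    def key(self) -> tuple:
        return (self.site, self.habitat, self.direction)

    def __len__(self) -> int:
        return len(self.responses)


@dataclass(frozen=True)
class HarmonizedScore:
    """A 5-point trend score with provenance, shared by both strands.

    ``source`` is ``"NS"`` or ``"CP"``; ``raw_median`` is the pre-rounding
    median (CP only, ``None`` for NS); ``n`` counts responses (CP) or
    year-on-year intervals (NS).
    """

    source: str
    site: str
    habitat: str
    direction: str
    score: int
    n: int
    raw_median: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source not in ("NS", "CP"):
            raise ValueError(f"source must be 'NS' or 'CP', got {self.source!r}")
        if self.score not in (-2, -1, 0, 1, 2):
            raise ValueError(f"score must be in -2..2, got {self.score}")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if self.raw_median is not None and not -2 <= self.raw_median <= 2:
            raise ValueError(
                f"raw_median must lie in [-2, 2], got {self.raw_median}"
            )

    @property
    def key(self) -> tuple:
        return (self.site, self.habitat, self.direction)


def map_likert7_to5(v: int) -> int:
    """Map a single 7-point response (-3..3) to the 5-point scale (-2..2)."""
    if isinstance(v, bool) or not isinstance(v, int) or v not in LIKERT7_TO_5:
        raise ValueError(
            f"7-point Likert response must be an integer in -3..3, got {v!r}"
        )
    return LIKERT7_TO_5[v]


def harmonize_sample(sample: SurveySample) -> list:
    """Return the sample's responses on the 5-point scale, order preserved.

    5-point responses pass through unchanged; 7-point responses are mapped
    element-wise via :func:`map_likert7_to5`.
    """
    if not sample.responses:
        raise ValueError(
            f"sample {sample.key} has no responses to harmonize"
        )
    if sample.scale_points == 5:
        return list(sample.responses)
    return [LIKERT7_TO_5[v] for v in sample.responses]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (2.5 -> 3)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def round_half_toward_zero(x: float) -> int:
    """Round to the nearest integer, halves toward zero (2.5 -> 2)."""
    return int(math.copysign(math.ceil(abs(x) - 0.5), x))


_ROUNDERS = {
    "half-away": round_half_away,
    "half-toward-zero": round_half_toward_zero,
}


def cp_trend_score(sample: SurveySample, rounding: str = "half-away") -> HarmonizedScore:
    """Reduce a survey sample to its 5-point comparison score.

    The median of the harmonized responses is the comparison score; a
    non-integer median (possible only for even sample sizes) is rounded
    per ``rounding`` — ``"half-away"`` (default, preserves the direction of
    the majority signal) or ``"half-toward-zero"``. The unrounded median
    is retained in ``raw_median``.
    """
    if rounding not in _ROUNDERS:
        raise ValueError(
            f"rounding must be one of {sorted(_ROUNDERS)}, got {rounding!r}"
        )
    harmonized = harmonize_sample(sample)
    raw_median = float(statistics.median(harmonized))
    if raw_median.is_integer():
        score = int(raw_median)
    else:
        score = _ROUNDERS[rounding](raw_median)
        logger.info(
            "rounded non-integer CP median %.1f to %d (%s) for %s",
            raw_median, score, rounding, sample.key,
        )
    return HarmonizedScore(
        source="CP",
        site=sample.site,
        habitat=sample.habitat,
        direction=sample.direction,
        score=score,
        n=len(sample),
        raw_median=raw_median,
    )
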