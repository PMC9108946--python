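"""NS - CP convergence/divergence scoring and matrix assembly.

Once both strands sit on the common 5-point scale, the community-
perception score is subtracted from the natural-science score, giving a
divergence ``d = ns - cp`` in -4..+4. Positive values mean the natural-
science data indicates a more positive trend than the community
perceives; negative values the reverse; 0 is full convergence.

``|d|`` classifies into bands (defaults, overridable per matrix):

    |d| = 0     full_convergence
    |d| = 1     strong_convergence
    |d| = 2     noticeable_divergence
    |d| >= 3    strong_divergence
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cp_scoring import HarmonizedScore

__all__ = [
    "BandCutoffs",
    "ConvergenceCell",
    "ConvergenceMatrix",
    "divergence",
    "classify_divergence",
    "build_matrix",
    "matrix_to_frame",
    "write_matrix_csv",
    "write_matrix_json",
]

BANDS = (
    "full_convergence",
    "strong_convergence",
    "noticeable_divergence",
    "strong_divergence",
)


@dataclass(frozen=True)
class BandCutoffs:
    """Configurable |d| cutoffs; defaults label |d|=2 as divergence."""

    noticeable_at: int = 2
    strong_at: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.noticeable_at <= self.strong_at <= 4:
            raise ValueError(
                f"need 1 <= noticeable_at <= strong_at <= 4, got "
                f"({self.noticeable_at}, {self.strong_at})"
            )


DEFAULT_BANDS = BandCutoffs()


def divergence(ns: int, cp: int) -> int:
    """The convergence/divergence score: NS score minus CP score."""
    if ns not in (-2, -1, 0, 1, 2) or cp not in (-2, -1, 0, 1, 2):
        raise ValueError(
            f"scores must be integers in -2..2, got ns={ns!r}, cp={cp!r}"
        )
    return ns - cp


def classify_divergence(d: int, cutoffs: BandCutoffs = DEFAULT_BANDS) -> str:
    """Band label for a divergence score; depends only on ``|d|``."""
    if d not in range(-4, 5):
        raise ValueError(f"divergence score must be an integer in -4..4, got {d!r}")
    a = abs(d)
    if a == 0:
        return "full_convergence"
    if a < cutoffs.noticeable_at:
        return "strong_convergence"
    if a < cutoffs.strong_at:
        return "noticeable_divergence"
    return "strong_divergence"


@dataclass(frozen=True)
class ConvergenceCell:
    """One site x habitat x direction cell of the comparison matrix.

    When either strand is absent the cell is ``missing`` and carries no
    divergence; missing pairings are preserved, never dropped, so the
    rendered matrix shows the data gaps.
    """

    site: str
    habitat: str
    direction: str
    ns_score: Optional[int] = None
    cp_score: Optional[int] = None
    d: Optional[int] = None
    band: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ns_score is not None and self.cp_score is not None:
            if self.d != self.ns_score - self.cp_score:
                raise ValueError(
                    f"cell {self.key}: d={self.d} inconsistent with "
                    f"ns-cp={self.ns_score - self.cp_score}"
                )
            if self.band not in BANDS:
                raise ValueError(f"cell {self.key}: invalid band {self.band!r}")
        elif self.d is not None or self.band is not None:
            raise ValueError(
                f"cell {self.key}: incomplete cells carry no d or band"
            )

    @property
    def key(self) -> tuple:
        return (self.site, self.habitat, self.direction)

    @property
    def missing(self) -> bool:
        return self.ns_score is None or self.cp_score is None


@dataclass(frozen=True)
class ConvergenceMatrix:
    """Sites (rows) x habitat-direction pairs (columns) of cells."""

    sites: tuple
    columns: tuple  # (habitat, direction) pairs
    cells: tuple
    band_cutoffs: BandCutoffs = DEFAULT_BANDS

    def cell(self, site: str, habitat: str, direction: str) -> Optional[ConvergenceCell]:
        for c in self.cells:
            if c.key == (site, habitat, direction):
                return c
        return None

    @property
    def complete_cells(self) -> list:
        return [c for c in self.cells if not c.missing]

    @property
    def legend(self) -> dict:
        return {
            "score_range": [-4, 4],
            "bands": {
                "full_convergence": "|d| = 0",
                "strong_convergence": f"0 < |d| < {self.band_cutoffs.noticeable_at}",
                "noticeable_divergence": (
                    f"{self.band_cutoffs.noticeable_at} <= |d| < "
                    f"{self.band_cutoffs.strong_at}"
                ),
                "strong_divergence": f"|d| >= {self.band_cutoffs.strong_at}",
            },
            "positive_d": "natural-science trend more positive than community perception",
            "negative_d": "community perception more positive than natural-science trend",
        }


def _ordered_unique(items: Iterable) -> list:
    seen = {}
    for x in items:
        seen.setdefault(x, None)
    return list(seen)


def build_matrix(
    ns_scores: Sequence[HarmonizedScore],
    cp_scores: Sequence[HarmonizedScore],
    band_cutoffs: BandCutoffs = DEFAULT_BANDS,
) -> ConvergenceMatrix:
    """Outer-join the two strands on (site, habitat, direction).

    Paired keys produce complete cells with ``d = ns - cp``; unpaired keys
    produce missing-flag cells. Row and column order follow first
    appearance (NS input first, then CP), so the layout is deterministic.
    A duplicate key on either side is an error naming the key.
    """
    ns_by_key = {}
    for s in ns_scores:
        if s.key in ns_by_key:
            raise ValueError(f"duplicate NS score for key {s.key}")
        ns_by_key[s.key] = s
    cp_by_key = {}
    for s in cp_scores:
        if s.key in cp_by_key:
            raise ValueError(f"duplicate CP score for key {s.key}")
        cp_by_key[s.key] = s

    all_keys = _ordered_unique(list(ns_by_key) + list(cp_by_key))
    cells = []
    for key in all_keys:
        site, habitat, direction = key
        ns = ns_by_key.get(key)
        cp = cp_by_key.get(key)
        if ns is not None and cp is not None:
            d = divergence(ns.score, cp.score)
            cells.append(
                ConvergenceCell(
                    site=site, habitat=habitat, direction=direction,
                    ns_score=ns.score, cp_score=cp.score,
                    d=d, band=classify_divergence(d, band_cutoffs),
                )
            )
        else:
            cells.append(
                ConvergenceCell(
                    site=site, habitat=habitat, direction=direction,
                    ns_score=None if ns is None else ns.score,
                    cp_score=None if cp is None else cp.score,
                )
            )
    sites = _ordered_unique(k[0] for k in all_keys)
    columns = _ordered_unique((k[1], k[2]) for k in all_keys)
    return ConvergenceMatrix(
        sites=tuple(sites),
        columns=tuple(columns),
        cells=tuple(cells),
        band_cutoffs=band_cutoffs,
    )


def matrix_to_frame(matrix: ConvergenceMatrix) -> pd.DataFrame:
    """Long-format DataFrame: site, habitat, direction, ns, cp, d, band."""
    rows = [
        {
            "site": c.site,
            "habitat": c.habitat,
            "direction": c.direction,
            "ns_score": c.ns_score,
            "cp_score": c.cp_score,
            "d": c.d,
            "band": c.band,
        }
        for c in matrix.cells
    ]
    return pd.DataFrame(
        rows,
        columns=["site", "habitat", "direction", "ns_score", "cp_score", "d", "band"],
    )


def write_matrix_csv(matrix: ConvergenceMatrix, path: str | Path) -> None:
    matrix_to_frame(matrix).to_csv(path, index=False)


def write_matrix_json(matrix: ConvergenceMatrix, path: str | Path) -> None:
    """JSON report: cells plus legend metadata."""
    payload = {
        "sites": list(matrix.sites),
        "columns": [list(c) for c in matrix.columns],
        # built from the cells directly so absent values serialize as null
        "cells": [
            {
                "site": c.site,
                "habitat": c.habitat,
                "direction": c.direction,
                "ns_score": c.ns_score,
                "cp_score": c.cp_score,
                "d": c.d,
                "band": c.band,
            }
            for c in matrix.cells
        ],
        "legend": matrix.legend,
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=False), encoding="utf-8"
    )
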