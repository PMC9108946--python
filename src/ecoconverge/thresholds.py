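"""Sector-specific category boundaries for annual rates of change.

Each sector maps a signed rate (% per year) to a trend score in {-2..+2}
through a symmetric pair of boundaries ``(inner, outer)``:

====================  =====================
rate                  score
====================  =====================
rate > outer          +2 (strong improvement)
inner < rate <= outer +1 (improvement)
-inner <= rate <= inner  0 (no or slight change)
-outer <= rate < -inner  -1 (decline)
rate < -outer         -2 (strong decline)
====================  =====================

The middle band is closed and the outer boundary value belongs to the
milder category, so a rate exactly at ``outer`` scores +1, not +2.

The shipped defaults encode the published calibration for Southeast Asian
coastal ecosystems: fisheries (10, 20) derived from the cross-site spread
of year-on-year landings change, mangrove (0.1, 0.5) from regional
deforestation-rate literature, coral (1, 2) from Indo-Pacific cover-loss
estimates, and seagrass (1, 5) from global seagrass decline rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "SectorThresholds",
    "ThresholdTable",
    "DEFAULT_THRESHOLDS",
    "SECTORS",
    "load_thresholds",
    "save_thresholds",
]

#: Closed vocabulary of threshold sectors. Aquaculture series are scored
#: with the fisheries boundaries (see :func:`ecoconverge.io.sector_for_habitat`).
SECTORS = ("fisheries", "mangrove", "coral", "seagrass")

VALID_PROVENANCE = ("literature", "median_derived", "user")


@dataclass(frozen=True)
class SectorThresholds:
    """Boundary pair for one sector, symmetric about zero."""

    inner: float
    outer: float
    provenance: str = "user"

    def __post_init__(self) -> None:
        if not (0 < self.inner < self.outer):
            raise ValueError(
                f"thresholds must satisfy 0 < inner < outer, "
                f"got inner={self.inner}, outer={self.outer}"
            )
        if self.provenance not in VALID_PROVENANCE:
            raise ValueError(
                f"unknown provenance {self.provenance!r}; "
                f"expected one of {VALID_PROVENANCE}"
            )


@dataclass(frozen=True)
class ThresholdTable:
    """Mapping sector tag -> :class:`SectorThresholds`."""

    sectors: Mapping[str, SectorThresholds] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.sectors:
            if name not in SECTORS:
                raise ValueError(
                    f"unknown sector {name!r}; expected one of {SECTORS}"
                )

    def __getitem__(self, sector: str) -> SectorThresholds:
        try:
            return self.sectors[sector]
        except KeyError:
            raise KeyError(
                f"sector {sector!r} not present in threshold table "
                f"(have: {sorted(self.sectors)})"
            ) from None

    def __contains__(self, sector: str) -> bool:
        return sector in self.sectors

    def to_dict(self) -> dict:
        return {
            name: {"inner": t.inner, "outer": t.outer, "provenance": t.provenance}
            for name, t in self.sectors.items()
        }


#: Published default boundaries, one column per sector.
DEFAULT_THRESHOLDS = ThresholdTable(
    {
        "fisheries": SectorThresholds(10.0, 20.0, "median_derived"),
        "mangrove": SectorThresholds(0.1, 0.5, "literature"),
        "coral": SectorThresholds(1.0, 2.0, "literature"),
        "seagrass": SectorThresholds(1.0, 5.0, "literature"),
    }
)


def load_thresholds(path: str | Path | None = None) -> ThresholdTable:
    """Load a threshold table from YAML/JSON, or return the packaged defaults.

    The file maps sector -> {inner, outer, provenance}. Validation errors
    (inner >= outer, unknown sector, bad provenance) raise ``ValueError``.
    """
    if path is None:
        return DEFAULT_THRESHOLDS
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"threshold file {path} must contain a mapping")
    sectors = {}
    for name, entry in raw.items():
        if not isinstance(entry, dict) or "inner" not in entry or "outer" not in entry:
            raise ValueError(
                f"sector {name!r} in {path} must be a mapping with "
                f"'inner' and 'outer' keys"
            )
        try:
            sectors[name] = SectorThresholds(
                float(entry["inner"]),
                float(entry["outer"]),
                str(entry.get("provenance", "user")),
            )
        except ValueError as exc:
            raise ValueError(f"sector {name!r} in {path}: {exc}") from exc
    return ThresholdTable(sectors)


def save_thresholds(table: ThresholdTable, path: str | Path) -> None:
    """Write a threshold table as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = table.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
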