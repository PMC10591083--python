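"""Range sizes and projected range changes under climate scenarios.

Given binary suitability cell sets for the current climate and a future
scenario (here RCP 2.6 and RCP 8.5, horizon 2070), two standard change
metrics are computed per taxon:

* with migration (full dispersal): the species can occupy any newly
  suitable cell, so the future range is the whole future suitable set;
* no migration (no dispersal): only cells suitable both now and in the
  future remain, i.e. the intersection with the current range.

Both are percentages of the current range size (cell counts on the
analysis lattice), rounded half-away-from-zero to one decimal place.
The no-migration change is necessarily in [-100, 0] and never exceeds
the with-migration change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .grid import CellSet

__all__ = [
    "RangeProjection",
    "RangeChangeRecord",
    "SCENARIOS",
    "range_size",
    "change_with_migration",
    "change_no_migration",
    "build_table",
]

SCENARIOS = ("RCP2.6", "RCP8.5")


@dataclass(frozen=True)
class RangeProjection:
    """Binary suitable-cell set for one taxon under one scenario."""

    taxon: str
    scenario: str  # "current" or one of SCENARIOS
    cells: frozenset
    horizon: int = 2070


@dataclass
class RangeChangeRecord:
    """One output row: current size plus four change percentages.

    ``change_mig`` / ``change_nomig`` map scenario name to percent.
    Taxa that could not be modelled carry ``reason`` instead.
    """

    taxon: str
    current_size: int | None = None
    change_mig: dict = field(default_factory=dict)
    change_nomig: dict = field(default_factory=dict)
    reason: str | None = None


def _round1(value: float) -> float:
    """Round half-away-from-zero to one decimal place."""
    return math.copysign(math.floor(abs(value) * 10 + 0.5) / 10, value)


def range_size(cells: CellSet) -> int:
    return len(cells)


def change_with_migration(current: CellSet, future: CellSet) -> float:
    """Percent range change assuming full migration potential."""
    if not current:
        raise ValueError("current range is empty; change undefined")
    return _round1(100.0 * (len(future) - len(current)) / len(current))


def change_no_migration(current: CellSet, future: CellSet) -> float:
    """Percent range change assuming no migration (retained cells only)."""
    if not current:
        raise ValueError("current range is empty; change undefined")
    retained = len(set(future) & set(current))
    return _round1(100.0 * (retained - len(current)) / len(current))


def build_table(projections: dict) -> list[RangeChangeRecord]:
    """Assemble per-taxon change records from projections.

    ``projections`` maps taxon name to either a reason string (taxon not
    modelled) or a mapping ``{"current": CellSet, scenario: CellSet, ...}``
    with at least the current projection.
    """
    records: list[RangeChangeRecord] = []
    for taxon, entry in projections.items():
        if isinstance(entry, str):
            records.append(RangeChangeRecord(taxon=taxon, reason=entry))
            continue
        if "current" not in entry:
            raise ValueError(f"taxon {taxon!r} lacks a current projection")
        current = entry["current"]
        record = RangeChangeRecord(taxon=taxon, current_size=len(current))
        for scenario in SCENARIOS:
            if scenario in entry:
                future = entry[scenario]
                record.change_mig[scenario] = change_with_migration(current, future)
                record.change_nomig[scenario] = change_no_migration(current, future)
        records.append(record)
    return records
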