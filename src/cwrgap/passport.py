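"""MCPD passport parsing and genebank representation statistics.

Reads EURISCO-style exports (Multi-Crop Passport Descriptors v2.1 column
vocabulary) and computes, per gene-pool taxon, the inventory statistics of
an ex situ gap analysis: total holdings, holdings collected in the native
range, per-country collection counts, country gaps, and tier-level
summaries such as the fraction of tertiary-pool taxa held in fewer than a
threshold number of accessions.

"Collected material" is operationalised through MCPD descriptors: a
record qualifies when COLLSRC indicates a wild/collecting source (codes
10-19) or, when COLLSRC is absent, SAMPSTAT lies in the wild range
(100-199).  Both code sets are configurable because passport files are
inconsistently populated.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .countries import is_alpha3
from .registry import Registry

__all__ = [
    "PassportRecord",
    "TaxonStats",
    "GenePoolSummary",
    "CollectedConfig",
    "PassportError",
    "parse_passport",
    "accession_counts",
    "native_collected_counts",
    "country_gaps",
    "summarize",
]

logger = logging.getLogger(__name__)


class PassportError(ValueError):
    """Raised for malformed passport files."""


@dataclass(frozen=True)
class PassportRecord:
    """One genebank accession (MCPD semantics)."""

    accenumb: str
    instcode: str = ""
    genus: str = ""
    species: str = ""
    spauthor: str = ""
    subtaxa: str = ""
    origcty: str = ""  # alpha-3 or "" when unknown
    collsrc: int | None = None
    sampstat: int | None = None

    @property
    def taxon_name(self) -> str:
        """"Genus species [authority]" as used for registry matching."""
        parts = [self.genus.strip(), self.species.strip()]
        if self.spauthor.strip():
            parts.append(self.spauthor.strip())
        return " ".join(p for p in parts if p)


@dataclass
class TaxonStats:
    """Representation of one taxon in the examined collections."""

    canonical_name: str
    total_accessions: int = 0
    native_collected: int = 0
    per_country_collected: dict = field(default_factory=dict)


@dataclass
class GenePoolSummary:
    """Tier-level inventory summary."""

    totals_by_tier: dict
    grand_total: int
    native_collected_total: int
    tertiary_fraction_below: dict  # threshold -> integer percent


@dataclass(frozen=True)
class CollectedConfig:
    """MCPD code sets that mark an accession as collected in the wild."""

    collsrc_codes: frozenset = frozenset(range(10, 20))
    sampstat_range: tuple = (100, 199)

    def qualifies(self, record: PassportRecord) -> bool:
        if record.collsrc is not None:
            return record.collsrc in self.collsrc_codes
        if record.sampstat is not None:
            lo, hi = self.sampstat_range
            return lo <= record.sampstat <= hi
        return False


def _to_int(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if not text:
        return None
    try:
        return int(float(text))
    except ValueError:
        return None


def parse_passport(source) -> list[PassportRecord]:
    """Parse an MCPD-dialect delimited file (path, file-like or DataFrame).

    Column headers are matched case-insensitively; unknown columns are
    ignored.  Rows with an unparseable ORIGCTY keep the record with
    origin unknown (logged).  A missing ACCENUMB column or duplicate
    (INSTCODE, ACCENUMB) pairs raise :class:`PassportError`.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    df.columns = [str(c).strip().upper() for c in df.columns]
    if "ACCENUMB" not in df.columns:
        raise PassportError("passport file lacks the ACCENUMB column")

    def col(name: str, row) -> str:
        value = row.get(name)
        if value is None or pd.isna(value):
            return ""
        return str(value).strip()

    records: list[PassportRecord] = []
    for _, row in df.iterrows():
        origcty = col("ORIGCTY", row).upper()
        if origcty and not is_alpha3(origcty):
            logger.warning("unparseable ORIGCTY %r; origin set unknown", origcty)
            origcty = ""
        records.append(
            PassportRecord(
                accenumb=col("ACCENUMB", row),
                instcode=col("INSTCODE", row),
                genus=col("GENUS", row),
                species=col("SPECIES", row),
                spauthor=col("SPAUTHOR", row),
                subtaxa=col("SUBTAXA", row),
                origcty=origcty,
                collsrc=_to_int(row.get("COLLSRC")),
                sampstat=_to_int(row.get("SAMPSTAT")),
            )
        )
    keys = Counter((r.instcode, r.accenumb) for r in records)
    dupes = sorted(k for k, n in keys.items() if n > 1)
    if dupes:
        raise PassportError(f"duplicate (INSTCODE, ACCENUMB) pairs: {dupes}")
    if any(not r.accenumb for r in records):
        raise PassportError("empty ACCENUMB in passport file")
    return records


def accession_counts(
    records: list[PassportRecord], registry: Registry
) -> tuple[dict, list[str]]:
    """Per-taxon accession totals, synonym-folded; subtaxa are ignored.

    Returns ``(counts, unmatched)`` where ``counts`` maps canonical names
    to record counts and ``unmatched`` lists taxon names that did not
    resolve against the registry.
    """
    counts: Counter = Counter()
    unmatched: list[str] = []
    for record in records:
        canon = registry.resolve(record.taxon_name)
        if canon is None:
            unmatched.append(record.taxon_name)
        else:
            counts[canon] += 1
    return dict(counts), unmatched


def native_collected_counts(
    records: list[PassportRecord],
    registry: Registry,
    config: CollectedConfig | None = None,
) -> dict:
    """Full per-taxon :class:`TaxonStats` from passport records.

    ``native_collected`` counts records whose origin country lies in the
    taxon's native range AND that qualify as collected material under
    ``config``.  Unknown-origin records count toward totals only.
    """
    config = config or CollectedConfig()
    stats: dict[str, TaxonStats] = {}
    for record in records:
        canon = registry.resolve(record.taxon_name)
        if canon is None:
            continue
        entry = stats.setdefault(canon, TaxonStats(canonical_name=canon))
        entry.total_accessions += 1
        if (
            record.origcty
            and record.origcty in registry.get(canon).native_countries
            and config.qualifies(record)
        ):
            entry.native_collected += 1
            entry.per_country_collected[record.origcty] = (
                entry.per_country_collected.get(record.origcty, 0) + 1
            )
    return stats


def country_gaps(stats: TaxonStats, registry: Registry) -> set:
    """Native-range countries with no collected accession at all."""
    native = registry.get(stats.canonical_name).native_countries
    return {c for c in native if stats.per_country_collected.get(c, 0) == 0}


def summarize(
    stats_by_taxon: dict,
    registry: Registry,
    thresholds: tuple = (10, 20),
) -> GenePoolSummary:
    """Tier totals, grand total, native-collected total and the
    percentage of tertiary-pool taxa below each accession-count
    threshold (rounded to the nearest integer percent)."""
    totals_by_tier: dict[str, int] = {}
    native_total = 0
    tertiary_totals: list[int] = []
    for taxon in registry:
        entry = stats_by_taxon.get(taxon.canonical_name)
        total = entry.total_accessions if entry else 0
        native_total += entry.native_collected if entry else 0
        totals_by_tier[taxon.tier] = totals_by_tier.get(taxon.tier, 0) + total
        if taxon.tier == "tertiary":
            tertiary_totals.append(total)
    fractions = {}
    for t in thresholds:
        if tertiary_totals:
            share = 100.0 * sum(1 for n in tertiary_totals if n < t) / len(tertiary_totals)
        else:
            share = 100.0
        fractions[t] = int(round(share))
    return GenePoolSummary(
        totals_by_tier=totals_by_tier,
        grand_total=sum(totals_by_tier.values()),
        native_collected_total=native_total,
        tertiary_fraction_below=fractions,
    )
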