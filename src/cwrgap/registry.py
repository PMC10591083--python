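"""The gene-pool registry: taxa, tiers, synonyms, native ranges, Red List.

A registry is the inventory of a crop gene pool in the Harlan & de Wet
sense: the crop itself (primary pool) plus its wild relatives grouped by
crossability (secondary / tertiary).  Each taxon carries its accepted
binomial (with authority), known synonyms, the set of countries of native
occurrence (ISO 3166-1 alpha-3) and its IUCN Red List category.  Name
resolution folds synonyms into canonical names, with an optional
authority-stripped fallback because passport data routinely omits
authorities.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .countries import to_alpha3

__all__ = [
    "Taxon",
    "Registry",
    "RegistryError",
    "load_registry",
    "write_registry",
    "resolve_name",
    "native_countries",
    "strip_authority",
]

logger = logging.getLogger(__name__)

TIERS = ("primary", "secondary", "tertiary")
CULTIVATION = ("wild", "cultivated", "partly_cultivated")
REDLIST = ("EN", "NT", "LC", "DD", "NOT_LISTED")

_REDLIST_TEXT = {
    "endangered": "EN",
    "near threatened": "NT",
    "least concern": "LC",
    "data deficient": "DD",
    "": "NOT_LISTED",
    "-": "NOT_LISTED",
    "–": "NOT_LISTED",
    "not listed": "NOT_LISTED",
}

_RANK_MARKERS = {"subsp.", "ssp.", "var.", "subvar.", "f.", "subf."}


class RegistryError(ValueError):
    """Raised for malformed or inconsistent registry sources."""


def _normalize(name: str) -> str:
    return re.sub(r"\s+", " ", name).strip()


def strip_authority(name: str) -> str:
    """Reduce a botanical name to genus + epithet (+ infraspecific part).

    "Hirschfeldia incana (L.) Lagr.-Foss." -> "Hirschfeldia incana";
    "Brassica souliei Batt. subsp. souliei Batt." ->
    "Brassica souliei subsp. souliei".
    """
    tokens = _normalize(name).split()
    if len(tokens) < 2:
        return _normalize(name)
    out = tokens[:2]
    i = 2
    while i < len(tokens):
        if tokens[i].lower() in _RANK_MARKERS and i + 1 < len(tokens):
            out.extend([tokens[i].lower(), tokens[i + 1]])
            i += 2
        else:
            i += 1
    return " ".join(out)


@dataclass(frozen=True)
class Taxon:
    """One member of the gene pool."""

    canonical_name: str
    tier: str
    cultivation: str = "wild"
    native_countries: frozenset = frozenset()
    redlist: str = "NOT_LISTED"
    synonyms: frozenset = frozenset()
    modellable_note: str | None = None  # ok / outside_study_area / insufficient_records / cultivated

    def __post_init__(self) -> None:
        if not self.canonical_name.strip():
            raise RegistryError("canonical_name must be nonempty")
        if self.tier not in TIERS:
            raise RegistryError(f"unknown tier {self.tier!r}")
        if self.cultivation not in CULTIVATION:
            raise RegistryError(f"unknown cultivation {self.cultivation!r}")
        if self.redlist not in REDLIST:
            raise RegistryError(f"unknown Red List category {self.redlist!r}")
        if self.canonical_name in self.synonyms:
            raise RegistryError(
                f"{self.canonical_name!r} listed among its own synonyms"
            )

    @property
    def genus(self) -> str:
        return self.canonical_name.split()[0]


class Registry:
    """Indexed collection of taxa with synonym-aware name resolution."""

    def __init__(self, taxa: list[Taxon]):
        if not taxa:
            raise RegistryError("registry must contain at least one taxon")
        self.taxa = list(taxa)
        self.name_index: dict[str, str] = {}
        self._by_canonical: dict[str, Taxon] = {}
        for taxon in self.taxa:
            canon = _normalize(taxon.canonical_name)
            if canon in self._by_canonical:
                raise RegistryError(f"duplicate canonical name {canon!r}")
            self._by_canonical[canon] = taxon
        for taxon in self.taxa:
            canon = _normalize(taxon.canonical_name)
            self._add_name(canon, canon)
            for syn in taxon.synonyms:
                self._add_name(_normalize(syn), canon)
        # authority-stripped fallback index; ambiguous stripped forms are
        # dropped so the fallback can never silently pick a wrong taxon
        self._stripped: dict[str, str | None] = {}
        for name, canon in self.name_index.items():
            key = strip_authority(name)
            if key in self._stripped and self._stripped[key] != canon:
                self._stripped[key] = None
            else:
                self._stripped[key] = canon

    def _add_name(self, name: str, canonical: str) -> None:
        existing = self.name_index.get(name)
        if existing is not None and existing != canonical:
            raise RegistryError(
                f"name {name!r} maps to both {existing!r} and {canonical!r}"
            )
        self.name_index[name] = canonical

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.taxa)

    def __iter__(self):
        return iter(self.taxa)

    def __eq__(self, other) -> bool:
        return isinstance(other, Registry) and sorted(
            self.taxa, key=lambda t: t.canonical_name
        ) == sorted(other.taxa, key=lambda t: t.canonical_name)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def genera(self) -> set:
        return {t.genus for t in self.taxa}

    @property
    def n_genera(self) -> int:
        return len(self.genera)

    def tier_counts(self) -> dict[str, int]:
        counts = {tier: 0 for tier in TIERS}
        for taxon in self.taxa:
            counts[taxon.tier] += 1
        return counts

    def get(self, canonical_name: str) -> Taxon:
        taxon = self._by_canonical.get(_normalize(canonical_name))
        if taxon is None:
            raise KeyError(f"unknown taxon {canonical_name!r}")
        return taxon

    def resolve(self, name: str, allow_stripped: bool = True) -> str | None:
        """Canonical name for ``name`` (canonical or synonym), else None.

        Exact match after whitespace normalisation; if that fails and
        ``allow_stripped`` is set, an authority-stripped match is
        attempted and logged.
        """
        norm = _normalize(name)
        if not norm:
            return None
        hit = self.name_index.get(norm)
        if hit is not None:
            return hit
        if allow_stripped:
            hit = self._stripped.get(strip_authority(norm))
            if hit is not None:
                logger.debug("authority-stripped match: %r -> %r", name, hit)
                return hit
        logger.debug("unresolved name: %r", name)
        return None


# -- module-level operations ------------------------------------------------


def resolve_name(name: str, registry: Registry) -> str | None:
    return registry.resolve(name)


def native_countries(canonical_name: str, registry: Registry) -> frozenset:
    canon = registry.resolve(canonical_name)
    if canon is None:
        raise KeyError(f"unknown taxon {canonical_name!r}")
    return registry.get(canon).native_countries


def _split_multi(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    return [part.strip() for part in str(value).split("|") if part.strip()]


def _parse_redlist(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return "NOT_LISTED"
    text = str(value).strip()
    if text.upper() in REDLIST:
        return text.upper()
    mapped = _REDLIST_TEXT.get(text.lower())
    if mapped is None:
        raise RegistryError(f"unknown Red List category {text!r}")
    return mapped


def load_registry(source) -> Registry:
    """Load a registry from a delimited table (path or DataFrame).

    Expected columns (case-insensitive): ``canonical_name`` (or
    ``taxon``), ``tier``, and optionally ``cultivation``,
    ``native_countries`` ("|"-separated names or alpha-3 codes),
    ``redlist``, ``synonyms`` ("|"-separated), ``modellable_note``.
    Country names are mapped to alpha-3 via the bundled lookup;
    unresolvable names raise, listing the offenders.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    if df.empty:
        raise RegistryError("registry source has no rows")
    df.columns = [str(c).strip().lower() for c in df.columns]
    name_col = "canonical_name" if "canonical_name" in df.columns else "taxon"
    if name_col not in df.columns or "tier" not in df.columns:
        raise RegistryError("registry needs 'canonical_name'/'taxon' and 'tier' columns")

    taxa: list[Taxon] = []
    bad_countries: list[str] = []
    for _, row in df.iterrows():
        codes = set()
        for item in _split_multi(row.get("native_countries")):
            code = to_alpha3(item)
            if code is None:
                bad_countries.append(item)
            else:
                codes.add(code)
        cultivation = str(row.get("cultivation") or "wild").strip() or "wild"
        note = row.get("modellable_note")
        note = None if note is None or pd.isna(note) or not str(note).strip() else str(note).strip()
        taxa.append(
            Taxon(
                canonical_name=_normalize(str(row[name_col])),
                tier=str(row["tier"]).strip().lower(),
                cultivation=cultivation,
                native_countries=frozenset(codes),
                redlist=_parse_redlist(row.get("redlist")),
                synonyms=frozenset(_split_multi(row.get("synonyms"))),
                modellable_note=note,
            )
        )
    if bad_countries:
        raise RegistryError(
            "unresolvable country names: " + ", ".join(sorted(set(bad_countries)))
        )
    return Registry(taxa)


def write_registry(registry: Registry, path) -> Path:
    """Write a registry as a TSV that :func:`load_registry` round-trips."""
    rows = []
    for taxon in registry:
        rows.append(
            {
                "canonical_name": taxon.canonical_name,
                "tier": taxon.tier,
                "cultivation": taxon.cultivation,
                "native_countries": "|".join(sorted(taxon.native_countries)),
                "redlist": taxon.redlist,
                "synonyms": "|".join(sorted(taxon.synonyms)),
                "modellable_note": taxon.modellable_note or "",
            }
        )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
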