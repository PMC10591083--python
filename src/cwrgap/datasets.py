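"""Packaged reference tables for the rapeseed gene pool.

Two delimited-text fixtures ship with the package:

* ``table1_genepool.tsv`` — the gene-pool inventory: 51 taxa across 16
  genera with tier, cultivation status, native-range countries, total
  European genebank holdings, holdings collected in the native range and
  IUCN Red List category.
* ``table2_range_change.tsv`` — per-taxon current range size (cells) and
  projected percent range change under RCP 2.6 / RCP 8.5, with and
  without migration, for 2070; taxa that could not be modelled carry the
  reason instead.

Each loader verifies the file's SHA-256 checksum against
``data/checksums.json`` so silent fixture corruption is caught early.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from .passport import TaxonStats
from .range_change import RangeChangeRecord
from .registry import Registry, load_registry

__all__ = ["load_genepool_registry", "load_genepool_stats", "load_range_change_table"]

_DATA = resources.files("cwrgap") / "data"


def _read_checked(filename: str) -> bytes:
    raw = (_DATA / filename).read_bytes()
    expected = json.loads((_DATA / "checksums.json").read_text())[filename]
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise RuntimeError(
            f"packaged fixture {filename} is corrupted "
            f"(sha256 {digest}, expected {expected})"
        )
    return raw


def _table1() -> pd.DataFrame:
    import io

    return pd.read_csv(io.BytesIO(_read_checked("table1_genepool.tsv")), sep="\t")


def load_genepool_registry() -> Registry:
    """The rapeseed gene-pool registry (taxa, tiers, ranges, Red List)."""
    return load_registry(_table1())


def load_genepool_stats() -> dict:
    """Per-taxon :class:`~cwrgap.passport.TaxonStats` from the packaged
    inventory (totals and native-collected counts as published; the
    per-country breakdown is not part of the published table)."""
    stats = {}
    for _, row in _table1().iterrows():
        stats[row["canonical_name"]] = TaxonStats(
            canonical_name=row["canonical_name"],
            total_accessions=int(row["accessions_total"]),
            native_collected=int(row["native_collected"]),
        )
    return stats


def load_range_change_table() -> list[RangeChangeRecord]:
    """The packaged range-change table as :class:`RangeChangeRecord` rows."""
    import io

    df = pd.read_csv(io.BytesIO(_read_checked("table2_range_change.tsv")), sep="\t")
    records = []
    for _, row in df.iterrows():
        if pd.isna(row["current_size"]):
            records.append(
                RangeChangeRecord(taxon=row["taxon"], reason=str(row["reason"]))
            )
        else:
            records.append(
                RangeChangeRecord(
                    taxon=row["taxon"],
                    current_size=int(row["current_size"]),
                    change_mig={
                        "RCP2.6": float(row["mig_rcp26"]),
                        "RCP8.5": float(row["mig_rcp85"]),
                    },
                    change_nomig={
                        "RCP2.6": float(row["nomig_rcp26"]),
                        "RCP8.5": float(row["nomig_rcp85"]),
                    },
                )
            )
    return records
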