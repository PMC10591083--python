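"""Rule-based collecting-priority classification.

Each gene-pool taxon is assigned to high / medium / low collecting
priority (or excluded) from three ingredients: its IUCN Red List
category, how many accessions were collected in its native range, and
the projected range loss under the pessimistic climate scenario
(RCP 8.5) assuming no migration.  The decision rules, in order:

1. **excluded** — cultivated or partly cultivated taxa, taxa outside the
   study area, and explicitly excluded names;
2. **high** — Red List category in the high set (default EN, NT): the
   Red List overrides everything else;
3. **high** — at most ``acc_floor_high`` (default 2) native-collected
   accessions;
4. **high** — projected RCP 8.5 no-migration loss of at least
   ``loss_high`` percent (default 60) while fewer than
   ``acc_cap_for_loss_rule`` (default 50) native-collected accessions;
5. **low** — at least ``acc_low`` (default 100) native-collected
   accessions;
6. **medium** — everything else.

All thresholds are configurable; each assignment records the rule that
fired so decisions stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .passport import TaxonStats
from .range_change import RangeChangeRecord
from .registry import Registry

__all__ = [
    "PriorityInput",
    "RuleConfig",
    "PriorityAssignment",
    "assign_priority",
    "build_priority_table",
    "DEFAULT_EXCLUSIONS",
]

#: Taxa excluded by name under the default rules (on top of the
#: cultivated and outside-study-area exclusions, which are flag-driven).
DEFAULT_EXCLUSIONS = frozenset({"Sinapis alba L.", "Raphanus raphanistrum L."})


@dataclass(frozen=True)
class PriorityInput:
    taxon: str
    redlist: str = "NOT_LISTED"
    cultivation: str = "wild"
    native_collected: int = 0
    loss_rcp85_nomig: float | None = None  # percent, negative = loss
    outside_study_area: bool = False


@dataclass(frozen=True)
class RuleConfig:
    redlist_high: frozenset = frozenset({"EN", "NT"})
    acc_floor_high: int = 2
    loss_high: float = 60.0
    acc_cap_for_loss_rule: int = 50
    acc_low: int = 100
    exclusions: frozenset = DEFAULT_EXCLUSIONS

    def __post_init__(self) -> None:
        if not (self.acc_floor_high < self.acc_cap_for_loss_rule < self.acc_low):
            raise ValueError(
                "rule thresholds must satisfy "
                "acc_floor_high < acc_cap_for_loss_rule < acc_low"
            )


@dataclass(frozen=True)
class PriorityAssignment:
    taxon: str
    category: str  # high | medium | low | excluded
    rule_fired: str


def assign_priority(inp: PriorityInput, rules: RuleConfig | None = None) -> PriorityAssignment:
    """Apply the decision rules (see module docstring) to one taxon."""
    rules = rules or RuleConfig()
    if inp.cultivation in ("cultivated", "partly_cultivated"):
        return PriorityAssignment(inp.taxon, "excluded", f"excluded:{inp.cultivation}")
    if inp.taxon in rules.exclusions:
        return PriorityAssignment(inp.taxon, "excluded", "excluded:listed")
    if inp.outside_study_area:
        return PriorityAssignment(inp.taxon, "excluded", "excluded:outside_study_area")
    if inp.redlist in rules.redlist_high:
        return PriorityAssignment(inp.taxon, "high", f"redlist:{inp.redlist}")
    if inp.native_collected <= rules.acc_floor_high:
        return PriorityAssignment(
            inp.taxon, "high", f"native_collected<={rules.acc_floor_high}"
        )
    if (
        inp.loss_rcp85_nomig is not None
        and abs(inp.loss_rcp85_nomig) >= rules.loss_high
        and inp.native_collected < rules.acc_cap_for_loss_rule
    ):
        return PriorityAssignment(
            inp.taxon,
            "high",
            f"loss>={rules.loss_high}%&native_collected<{rules.acc_cap_for_loss_rule}",
        )
    if inp.native_collected >= rules.acc_low:
        return PriorityAssignment(inp.taxon, "low", f"native_collected>={rules.acc_low}")
    return PriorityAssignment(inp.taxon, "medium", "default")


def build_priority_table(
    registry: Registry,
    stats: dict,
    range_table: list[RangeChangeRecord],
    rules: RuleConfig | None = None,
) -> list[PriorityAssignment]:
    """One assignment per registry taxon.

    ``stats`` maps canonical names to :class:`TaxonStats` (missing taxa
    count as zero native-collected); ``range_table`` supplies the
    RCP 8.5 no-migration loss where the taxon was modelled.
    """
    rules = rules or RuleConfig()
    loss_by_taxon: dict[str, float] = {}
    for record in range_table:
        if record.reason is None and "RCP8.5" in record.change_nomig:
            loss_by_taxon[record.taxon] = record.change_nomig["RCP8.5"]
    assignments = []
    for taxon in registry:
        entry: TaxonStats | None = stats.get(taxon.canonical_name)
        assignments.append(
            assign_priority(
                PriorityInput(
                    taxon=taxon.canonical_name,
                    redlist=taxon.redlist,
                    cultivation=taxon.cultivation,
                    native_collected=entry.native_collected if entry else 0,
                    loss_rcp85_nomig=loss_by_taxon.get(taxon.canonical_name),
                    outside_study_area=taxon.modellable_note == "outside_study_area",
                ),
                rules,
            )
        )
    return assignments
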