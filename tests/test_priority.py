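"""Collecting-priority rules: published assignments and rule properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cwrgap.priority import (
    PriorityInput,
    RuleConfig,
    assign_priority,
    build_priority_table,
)
from cwrgap.registry import Registry, Taxon

RANK = {"excluded": -1, "low": 0, "medium": 1, "high": 2}

EXPECTED_CATEGORIES = {
    # published priority list: 18 high, 17 medium, 3 low
    "Brassica deserti Danin & Hedge": "high",
    "Brassica desnottesii Emb. & Maire": "high",
    "Brassica dimorpha Coss. & Durieu": "high",
    "Brassica elongata Ehrh.": "high",
    "Brassica fruticulosa Cirillo": "high",
    "Brassica gravinae Ten.": "high",
    "Brassica hilarionis Post": "high",
    "Brassica insularis Moris": "high",
    "Brassica maurorum Durieu": "high",
    "Brassica montana Pourr.": "high",
    "Brassica repanda (Willd.) DC.": "high",
    "Brassica souliei Batt. subsp. amplexicaulis (Desf.) Greuter & Burdet": "high",
    "Brassica souliei Batt. subsp. souliei Batt.": "high",
    "Descurainia sophia (L.) Webb ex Prantl": "high",
    "Diplotaxis siifolia Kunze": "high",
    "Enarthrocarpus lyratus (Forssk.) DC.": "high",
    "Erucastrum gallicum (Willd.) O. E. Schulz": "high",
    "Rorippa islandica (Oeder) Borb": "high",
    "Brassica bourgeaui (Webb ex Christ) Kuntze": "medium",
    "Brassica cretica Lam.": "medium",
    "Brassica incana Ten.": "medium",
    "Brassica nigra (L.) W. D. J. Koch": "medium",
    "Capsella bursa-pastoris (L.) Medik.": "medium",
    "Diplotaxis acris (Forsk.) Boiss.": "medium",
    "Diplotaxis catholica (L.) DC.": "medium",
    "Diplotaxis erucoides (L.) DC.": "medium",
    "Diplotaxis harra (Forssk.) Boiss.": "medium",
    "Diplotaxis muralis (L.) DC.": "medium",
    "Diplotaxis tenuifolia (L.) DC.": "medium",
    "Diplotaxis viminea (L.) DC.": "medium",
    "Moricandia arvensis (L.) DC.": "medium",
    "Moricandia nitens (Viv.) E. A. Durand & Barratte": "medium",
    "Rapistrum rugosum (L.) All.": "medium",
    "Sinapis arvensis L.": "medium",
    "Sinapis pubescens L.": "medium",
    "Brassica tournefortii Gouan": "low",
    "Eruca vesicaria (L.) Cav.": "low",
    "Hirschfeldia incana (L.) Lagr.-Foss.": "low",
}


class TestSingleAssignments:
    def test_near_threatened_is_high_despite_holdings(self):
        a = assign_priority(
            PriorityInput("Brassica insularis Moris", redlist="NT", native_collected=31,
                          loss_rcp85_nomig=-89.0)
        )
        assert a.category == "high"
        assert a.rule_fired.startswith("redlist")

    def test_well_represented_is_low(self):
        a = assign_priority(
            PriorityInput("Brassica tournefortii Gouan", redlist="LC",
                          native_collected=111, loss_rcp85_nomig=-23.3)
        )
        assert a.category == "low"

    def test_few_accessions_with_modest_loss_is_medium(self):
        a = assign_priority(
            PriorityInput("Diplotaxis viminea (L.) DC.", redlist="LC",
                          native_collected=3, loss_rcp85_nomig=-28.6)
        )
        assert a.category == "medium"

    def test_partly_cultivated_is_excluded(self):
        a = assign_priority(
            PriorityInput("Brassica rapa L.", redlist="DD",
                          cultivation="partly_cultivated", native_collected=1231)
        )
        assert a.category == "excluded"

    def test_severe_loss_with_large_holdings_stays_medium(self):
        # the loss rule only fires below the holdings cap
        a = assign_priority(
            PriorityInput("Brassica cretica Lam.", redlist="LC",
                          native_collected=97, loss_rcp85_nomig=-63.7)
        )
        assert a.category == "medium"

    def test_unmodelled_sparse_taxon_reaches_high(self):
        a = assign_priority(
            PriorityInput("Brassica deserti Danin & Hedge", native_collected=0,
                          loss_rcp85_nomig=None)
        )
        assert a.category == "high"


class TestPublishedPriorityList:
    def test_all_38_published_rows_match(self, registry, genepool_stats, range_table):
        assignments = {
            a.taxon: a.category
            for a in build_priority_table(registry, genepool_stats, range_table)
        }
        mismatches = {
            name: (assignments.get(name), cat)
            for name, cat in EXPECTED_CATEGORIES.items()
            if assignments.get(name) != cat
        }
        assert mismatches == {}

    def test_18_high_priority_taxa(self, registry, genepool_stats, range_table):
        assignments = build_priority_table(registry, genepool_stats, range_table)
        assert sum(a.category == "high" for a in assignments) == 18

    def test_13_exclusions(self, registry, genepool_stats, range_table):
        assignments = build_priority_table(registry, genepool_stats, range_table)
        excluded = {a.taxon for a in assignments if a.category == "excluded"}
        assert len(excluded) == 13
        assert "Brassica rapa L." in excluded
        assert "Sinapis alba L." in excluded
        assert "Raphanus raphanistrum L." in excluded

    def test_cultivated_only_registry_all_excluded(self, genepool_stats):
        taxa = [
            Taxon("Brassica napus L.", "primary", cultivation="cultivated"),
            Taxon("Brassica juncea (L.) Czern.", "secondary", cultivation="cultivated"),
        ]
        assignments = build_priority_table(Registry(taxa), {}, [])
        assert all(a.category == "excluded" for a in assignments)


inputs = st.builds(
    PriorityInput,
    taxon=st.just("Random taxon L."),
    redlist=st.sampled_from(["EN", "NT", "LC", "DD", "NOT_LISTED"]),
    cultivation=st.just("wild"),
    native_collected=st.integers(0, 500),
    loss_rcp85_nomig=st.one_of(st.none(), st.floats(-100.0, 0.0)),
)


class TestRuleProperties:
    @settings(max_examples=300, derandomize=True)
    @given(inp=inputs)
    def test_redlist_override(self, inp):
        """EN/NT always classify high, whatever the other fields say."""
        a = assign_priority(inp)
        if inp.redlist in ("EN", "NT"):
            assert a.category == "high"

    @settings(max_examples=300, derandomize=True)
    @given(inp=inputs)
    def test_fewer_accessions_never_lower_priority(self, inp):
        if inp.native_collected == 0:
            return
        fewer = PriorityInput(
            inp.taxon, inp.redlist, inp.cultivation,
            inp.native_collected - 1, inp.loss_rcp85_nomig,
        )
        assert RANK[assign_priority(fewer).category] >= RANK[assign_priority(inp).category]

    @settings(max_examples=300, derandomize=True)
    @given(inp=inputs, extra=st.floats(0.0, 50.0))
    def test_larger_loss_never_lowers_priority(self, inp, extra):
        if inp.loss_rcp85_nomig is None:
            return
        worse = PriorityInput(
            inp.taxon, inp.redlist, inp.cultivation, inp.native_collected,
            max(inp.loss_rcp85_nomig - extra, -100.0),
        )
        assert RANK[assign_priority(worse).category] >= RANK[assign_priority(inp).category]


def test_invalid_threshold_ordering_rejected():
    with pytest.raises(ValueError):
        RuleConfig(acc_floor_high=60, acc_cap_for_loss_rule=50)
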