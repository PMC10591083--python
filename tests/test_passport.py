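"""MCPD passport parsing and representation statistics."""

import io

import pytest

from cwrgap.passport import (
    CollectedConfig,
    PassportError,
    TaxonStats,
    accession_counts,
    country_gaps,
    native_collected_counts,
    parse_passport,
    summarize,
)
from cwrgap.synthetic import make_passport_file

HEADER = "INSTCODE\tACCENUMB\tGENUS\tSPECIES\tSPAUTHOR\tORIGCTY\tCOLLSRC\tSAMPSTAT\n"


def _parse(text: str):
    return parse_passport(io.StringIO(text))


class TestParsing:
    def test_well_formed_rows_parse(self):
        records = _parse(
            HEADER
            + "NLD037\tA1\tBrassica\trapa\tL.\tFRA\t20\t\n"
            + "NLD037\tA2\tBrassica\trapa\tL.\tESP\t\t100\n"
        )
        assert len(records) == 2
        assert records[0].origcty == "FRA"
        assert records[1].sampstat == 100

    def test_empty_origin_kept_as_unknown(self):
        records = _parse(HEADER + "NLD037\tA1\tBrassica\trapa\tL.\t\t\t\n")
        assert len(records) == 1
        assert records[0].origcty == ""

    def test_bad_origin_kept_as_unknown(self):
        records = _parse(HEADER + "NLD037\tA1\tBrassica\trapa\tL.\tFrankreich\t\t\n")
        assert records[0].origcty == ""

    def test_missing_accenumb_column_rejected(self):
        with pytest.raises(PassportError, match="ACCENUMB"):
            _parse("INSTCODE\tGENUS\nNLD037\tBrassica\n")

    def test_duplicate_accession_rejected(self):
        with pytest.raises(PassportError, match="duplicate"):
            _parse(
                HEADER
                + "NLD037\tA1\tBrassica\trapa\tL.\tFRA\t20\t\n"
                + "NLD037\tA1\tBrassica\trapa\tL.\tESP\t20\t\n"
            )


class TestCollectedConfig:
    @pytest.mark.parametrize(
        "collsrc, sampstat, expected",
        [
            (10, None, True),   # wild habitat collecting source
            (19, None, True),
            (20, None, False),  # farm / market source
            (None, 100, True),  # wild biological status
            (None, 300, False),
            (20, 100, False),   # COLLSRC present and non-wild wins
            (None, None, False),
        ],
    )
    def test_collected_qualification(self, collsrc, sampstat, expected):
        from cwrgap.passport import PassportRecord

        record = PassportRecord(accenumb="x", collsrc=collsrc, sampstat=sampstat)
        assert CollectedConfig().qualifies(record) is expected


class TestCountsOnSyntheticFiles:
    """The generator's own tallies are the exact oracle."""

    SPEC = {
        "Brassica rapa L.": [
            {"origcty": "FRA", "n": 5, "collsrc": 10},      # native + collected
            {"origcty": "FRA", "n": 2, "collsrc": 20},      # native, not collected
            {"origcty": "EGY", "n": 3, "collsrc": 10},      # collected outside range
            {"origcty": "", "n": 4},                        # unknown origin
        ],
        "Sinapis incana L.": [                              # synonym label
            {"origcty": "GRC", "n": 2, "sampstat": 100},
        ],
    }

    @pytest.fixture
    def records(self, tmp_path):
        path, _ = make_passport_file(self.SPEC, tmp_path / "passport.tsv", seed=11)
        return parse_passport(path)

    def test_totals_fold_synonyms(self, registry, records):
        counts, unmatched = accession_counts(records, registry)
        assert counts["Brassica rapa L."] == 14
        assert counts["Hirschfeldia incana (L.) Lagr.-Foss."] == 2
        assert unmatched == []

    def test_native_collected_recovered_exactly(self, registry, records):
        stats = native_collected_counts(records, registry)
        rapa = stats["Brassica rapa L."]
        assert rapa.total_accessions == 14
        assert rapa.native_collected == 5
        assert rapa.per_country_collected == {"FRA": 5}
        hirsch = stats["Hirschfeldia incana (L.) Lagr.-Foss."]
        assert (hirsch.total_accessions, hirsch.native_collected) == (2, 2)

    def test_unknown_origin_never_counts_as_native(self, registry, records):
        stats = native_collected_counts(records, registry)
        for entry in stats.values():
            assert entry.native_collected <= entry.total_accessions
            assert sum(entry.per_country_collected.values()) == entry.native_collected

    def test_order_independence(self, registry, tmp_path):
        p1, _ = make_passport_file(self.SPEC, tmp_path / "a.tsv", seed=1)
        p2, _ = make_passport_file(self.SPEC, tmp_path / "b.tsv", seed=2)
        s1 = native_collected_counts(parse_passport(p1), registry)
        s2 = native_collected_counts(parse_passport(p2), registry)
        assert {k: (v.total_accessions, v.native_collected) for k, v in s1.items()} == {
            k: (v.total_accessions, v.native_collected) for k, v in s2.items()
        }


class TestCountryGaps:
    def test_gap_is_native_minus_collected(self, registry):
        stats = TaxonStats(
            "Brassica elongata Ehrh.",
            total_accessions=14,
            native_collected=4,
            per_country_collected={"ESP": 2, "HUN": 1, "UKR": 1},
        )
        gaps = country_gaps(stats, registry)
        assert len(gaps) == 14  # 17 native countries, 3 with collections
        assert gaps.isdisjoint({"ESP", "HUN", "UKR"})

    def test_no_collections_means_full_gap(self, registry):
        stats = TaxonStats("Descurainia sophia (L.) Webb ex Prantl")
        gaps = country_gaps(stats, registry)
        assert len(gaps) == 38

    def test_six_collected_countries_leave_32_gaps(self, registry):
        per_country = {c: 1 for c in ["FRA", "ESP", "ITA", "GRC", "HUN", "UKR"]}
        stats = TaxonStats(
            "Descurainia sophia (L.) Webb ex Prantl",
            total_accessions=22,
            native_collected=6,
            per_country_collected=per_country,
        )
        assert len(country_gaps(stats, registry)) == 32


class TestSummary:
    def test_packaged_inventory_summary(self, registry, genepool_stats):
        summary = summarize(genepool_stats, registry, thresholds=(10, 20))
        assert summary.grand_total == 34777
        assert summary.totals_by_tier == {
            "primary": 5922,
            "secondary": 9847,
            "tertiary": 19008,
        }
        assert summary.native_collected_total == 7001
        assert summary.tertiary_fraction_below == {10: 35, 20: 50}

    def test_grand_total_conserved(self, registry, genepool_stats):
        summary = summarize(genepool_stats, registry)
        assert summary.grand_total == sum(
            s.total_accessions for s in genepool_stats.values()
        )
        assert summary.grand_total == sum(summary.totals_by_tier.values())

    def test_all_zero_stats_degenerate(self, registry):
        summary = summarize({}, registry, thresholds=(10,))
        assert summary.grand_total == 0
        assert summary.native_collected_total == 0
        assert summary.tertiary_fraction_below == {10: 100}


def test_empty_spec_yields_header_only_file(tmp_path):
    path, truth = make_passport_file({}, tmp_path / "empty.tsv", seed=0)
    assert parse_passport(path) == []
    assert truth == {}
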