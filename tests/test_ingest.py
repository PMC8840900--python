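"""Survey ingestion: reading, census-unit conversion, filtering, biomass assembly."""

import numpy as np
import pandas as pd
import pytest

from forestbird.errors import (
    ConfigurationError,
    DataError,
    SpeciesLookupError,
    StateError,
)
from forestbird.ingest import (
    PointCountTable,
    apply_guild_filters,
    build_samples,
    merge_breeding_periods,
    pairs_to_individuals,
    read_point_counts,
)

DIALECT = {"site_id": "site", "point_id": "pt", "year": "yr",
           "species_code": "sp", "count": "n"}


def _write(tmp_path, text, name="counts.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPointCounts:
    def test_identity_read(self, tmp_path):
        p = _write(tmp_path, "site,pt,yr,sp,n\nA,1,2001,X,2\nA,2,2001,Y,0\nB,1,2002,X,5\n")
        tab = read_point_counts(p, DIALECT)
        assert len(tab) == 3
        assert tab.records["count"].tolist() == [2, 0, 5]

    def test_duplicate_keys_summed(self, tmp_path):
        p = _write(tmp_path, "site,pt,yr,sp,n\nA,1,2001,X,1\nA,1,2001,X,2\n")
        tab = read_point_counts(p, DIALECT)
        assert len(tab) == 1
        assert tab.records["count"].iloc[0] == 3

    def test_missing_column_mapping_is_config_error(self, tmp_path):
        p = _write(tmp_path, "site,pt,yr,n\nA,1,2001,2\n")
        with pytest.raises(ConfigurationError):
            read_point_counts(p, {k: v for k, v in DIALECT.items() if k != "species_code"})
        with pytest.raises(ConfigurationError):
            read_point_counts(p, DIALECT)  # mapped column absent from file

    def test_non_integer_count_is_parse_error(self, tmp_path):
        p = _write(tmp_path, "site,pt,yr,sp,n\nA,1,2001,X,2.5\n")
        with pytest.raises(DataError, match="row 0"):
            read_point_counts(p, DIALECT)


class TestPairsToIndividuals:
    def test_doubles_counts(self, tmp_path):
        p = _write(tmp_path, "site,pt,yr,sp,n\nA,1,2001,X,3\nA,1,2001,Y,0\n")
        tab = read_point_counts(p, DIALECT, country_mode="pair_counts")
        out = pairs_to_individuals(tab)
        assert out.records["count"].tolist() == [6, 0]
        assert out.country_mode == "individual_counts"

    def test_applying_twice_is_state_error(self, tmp_path):
        p = _write(tmp_path, "site,pt,yr,sp,n\nA,1,2001,X,3\n")
        tab = pairs_to_individuals(read_point_counts(p, DIALECT, country_mode="pair_counts"))
        with pytest.raises(StateError):
            pairs_to_individuals(tab)


class TestMergeBreedingPeriods:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["site_id", "point_id", "year", "period",
                                         "species_code", "count"])
        df["habitat_code"] = "F"
        return PointCountTable(records=df, country_mode="individual_counts")

    def test_periods_summed(self):
        tab = self._table([("A", "1", 2001, 1, "X", 2), ("A", "1", 2001, 2, "X", 5)])
        out = merge_breeding_periods(tab)
        assert len(out) == 1
        assert out.records["count"].iloc[0] == 7
        assert (out.records["period"] == 1).all()

    def test_single_period_identity(self):
        tab = self._table([("A", "1", 2001, 1, "X", 2), ("A", "1", 2001, 1, "Y", 4)])
        out = merge_breeding_periods(tab)
        assert out.records["count"].tolist() == [2, 4]

    def test_species_only_in_period_two_retained(self):
        rows = [("A", "1", 2001, 1, "X", 2), ("A", "1", 2001, 2, "Z", 3),
                ("A", "1", 2001, 2, "X", 1)]
        tab = self._table(rows)
        out = merge_breeding_periods(tab)
        # set-union oracle over (site, point, year, species) keys
        expect_keys = {("A", "1", 2001, "X"), ("A", "1", 2001, "Z")}
        got = set(map(tuple, out.records[["site_id", "point_id", "year",
                                          "species_code"]].to_numpy()))
        assert got == expect_keys
        assert out.records.set_index("species_code")["count"].to_dict() == {"X": 3, "Z": 3}


class TestGuildFilters:
    def test_excluded_and_nonforest_removed(self, toy_records, toy_traits):
        out = apply_guild_filters(toy_records, toy_traits)
        assert set(out.records["species_code"]) == {"TIT1", "WARB"}

    def test_identity_when_all_forest(self, toy_records, toy_traits):
        traits = toy_traits.copy()
        traits["is_excluded_guild"] = False
        traits["is_forest"] = True
        out = apply_guild_filters(toy_records, traits)
        assert len(out) == len(toy_records)

    def test_unknown_species_is_lookup_error(self, toy_records, toy_traits):
        with pytest.raises(SpeciesLookupError, match="WADER"):
            apply_guild_filters(toy_records, toy_traits.drop(index="WADER"))


class TestBuildSamples:
    def test_hand_summed_biomass(self, toy_records, toy_traits, toy_locations):
        filtered = apply_guild_filters(toy_records, toy_traits)
        s = build_samples(filtered, toy_traits, toy_locations)
        # 2 titmice x 10 g, 3 warblers x 20 g
        assert s["tit"].iloc[0] == 20.0
        assert s["b"].iloc[0] == 60.0
        assert s["a"].iloc[0] == 0.031

    def test_empty_point_year_zeroes(self, toy_traits, toy_locations):
        rec = pd.DataFrame({
            "site_id": ["A"], "point_id": ["p1"], "year": [2001], "period": [1],
            "species_code": ["WARB"], "count": [0], "habitat_code": ["F"],
        })
        tab = PointCountTable(records=rec, country_mode="individual_counts")
        s = build_samples(tab, toy_traits, toy_locations)
        assert s["b"].iloc[0] == 0.0 and s["tit"].iloc[0] == 0.0

    def test_control_exclusion(self, toy_records, toy_traits, toy_locations):
        filtered = apply_guild_filters(toy_records, toy_traits)
        s = build_samples(filtered, toy_traits, toy_locations,
                          control_species={"WARB"})
        assert s["b"].iloc[0] == 0.0
        assert s["control"].iloc[0] == 60.0
        assert s["tit"].iloc[0] == 20.0

    def test_control_overlapping_titmice_is_config_error(
        self, toy_records, toy_traits, toy_locations
    ):
        with pytest.raises(ConfigurationError):
            build_samples(toy_records, toy_traits, toy_locations,
                          control_species={"TIT1"})


class TestInvariants:
    def test_total_biomass_conservation(self, community_dataset, toy_locations):
        """Σ(b + tit + control) equals Σ count x mass over retained records exactly."""
        _, ds = community_dataset
        tab = PointCountTable(records=ds.records, country_mode="individual_counts")
        filtered = apply_guild_filters(tab, ds.traits)
        ctrl = set(ds.traits.index[~ds.traits["is_titmouse"]][:3])
        s = build_samples(filtered, ds.traits, ds.locations, control_species=ctrl)
        total_samples = (s["b"] + s["tit"] + s["control"]).sum()
        tr = ds.traits.loc[filtered.records["species_code"]]
        total_records = (filtered.records["count"].to_numpy() * tr["body_mass"].to_numpy()).sum()
        assert total_samples == pytest.approx(total_records, rel=1e-12)

    def test_pair_doubling_doubles_biomass(self, toy_traits, toy_locations):
        rec = pd.DataFrame({
            "site_id": ["A", "A"], "point_id": ["p1", "p1"], "year": [2001, 2001],
            "period": [1, 1], "species_code": ["TIT1", "WARB"], "count": [2, 3],
            "habitat_code": ["F", "F"],
        })
        as_pairs = PointCountTable(records=rec, country_mode="pair_counts")
        doubled = pairs_to_individuals(as_pairs)
        as_is = PointCountTable(records=rec, country_mode="individual_counts")
        s2 = build_samples(doubled, toy_traits, toy_locations)
        s1 = build_samples(as_is, toy_traits, toy_locations)
        assert s2["b"].iloc[0] == 2 * s1["b"].iloc[0]
        assert s2["tit"].iloc[0] == 2 * s1["tit"].iloc[0]

    def test_period_merge_commutes_with_guild_filter(self, toy_traits):
        rec = pd.DataFrame({
            "site_id": ["A"] * 4, "point_id": ["p1"] * 4, "year": [2001] * 4,
            "period": [1, 2, 1, 2],
            "species_code": ["WARB", "WARB", "WADER", "TIT1"],
            "count": [1, 2, 3, 4], "habitat_code": ["F"] * 4,
        })
        tab = PointCountTable(records=rec, country_mode="individual_counts")
        a = apply_guild_filters(merge_breeding_periods(tab), toy_traits)
        b = merge_breeding_periods(apply_guild_filters(tab, toy_traits))
        key = ["site_id", "point_id", "year", "period", "species_code"]
        pd.testing.assert_frame_equal(
            a.records.sort_values(key).reset_index(drop=True)[key + ["count"]],
            b.records.sort_values(key).reset_index(drop=True)[key + ["count"]],
        )
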