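"""Cleaning, harmonization, unit normalization and MRL matching."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vegrisk import (
    ConfigError,
    DataError,
    InspectionRecord,
    MRLEntry,
    MRLTable,
    ResidueMeasurement,
    UNMAPPED,
    canonicalize_name,
    match_mrl,
    normalize_concentration,
    read_records,
    records_to_frame,
)
from vegrisk.ingest import BANNED, LIMIT, NO_LIMIT, CleaningConfig
from vegrisk.names import PESTICIDE_DICT, VEGETABLE_DICT

COLS = ["province", "vegetable", "year", "batch_id", "pesticide",
        "concentration", "unit"]


class TestReadRecords:
    def test_empty_table_yields_no_records(self):
        records, report = read_records(pd.DataFrame(columns=COLS))
        assert records == [] and report.n_read == 0

    def test_hand_counted_fixture(self, mixed_records):
        """10 rows, 2 malformed -> 8 kept rows forming 7 batches; counts balance."""
        records, report = mixed_records
        assert report.n_read == 10
        assert report.n_kept == 8
        assert report.n_dropped_missing == 2  # blank concentration + bad unit
        assert report.n_read == report.n_kept + report.n_dropped
        assert len(records) == 7

    def test_no_detection_row_keeps_batch_with_empty_panel(self, mixed_records):
        records, _ = mixed_records
        b3 = next(r for r in records if r.batch_id == "b3")
        assert b3.measurements == ()

    def test_unit_conversion_applied_and_counted(self, mixed_records):
        records, report = mixed_records
        b1 = next(r for r in records if r.batch_id == "b1")
        by_pest = {m.pesticide: m.concentration for m in b1.measurements}
        assert by_pest["imidacloprid"] == pytest.approx(0.5)  # 500 µg/kg
        assert report.n_unit_converted == 1  # ppm is already mg/kg-equivalent

    def test_alias_is_harmonized(self, mixed_records):
        records, _ = mixed_records
        b7 = next(r for r in records if r.batch_id == "b7")
        assert b7.vegetable == "pepper"  # "chili" collapses to the canonical name

    def test_unmapped_vegetable_is_counted_drop(self):
        df = pd.DataFrame(
            [("Jiangsu", "dragonfruit", 2021, "x1", "imidacloprid", "0.1", "mg/kg")],
            columns=COLS,
        )
        records, report = read_records(df)
        assert records == [] and report.n_dropped_unmapped_name == 1

    def test_year_outside_window_dropped(self):
        df = pd.DataFrame(
            [("Jiangsu", "celery", 2015, "x1", "imidacloprid", "0.1", "mg/kg")],
            columns=COLS,
        )
        records, report = read_records(df)
        assert records == [] and report.n_dropped == 1

    def test_duplicate_batch_with_conflicting_keys_is_fatal(self):
        df = pd.DataFrame(
            [
                ("Jiangsu", "celery", 2021, "x1", "imidacloprid", "0.1", "mg/kg"),
                ("Yunnan", "celery", 2021, "x1", "imidacloprid", "0.1", "mg/kg"),
            ],
            columns=COLS,
        )
        with pytest.raises(DataError, match="duplicate batch_id"):
            read_records(df)

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(DataError, match="not found"):
            read_records(tmp_path / "nope.csv")

    def test_missing_column_is_config_error(self):
        with pytest.raises(ConfigError, match="required columns"):
            read_records(pd.DataFrame(columns=COLS[:-1]))

    def test_outlier_cap_drops_and_counts(self, small_mrl_table):
        df = pd.DataFrame(
            [("Jiangsu", "leek", 2021, "x1", "procymidone", "400", "mg/kg")],
            columns=COLS,
        )  # 2000x the 0.2 mg/kg limit
        records, report = read_records(
            df, cleaning=CleaningConfig(outlier_cap=1000), mrl_table=small_mrl_table
        )
        assert report.n_dropped_outlier == 1 and records == []
        # default: cap off, the measurement survives
        records, report = read_records(df, mrl_table=small_mrl_table)
        assert report.n_dropped_outlier == 0 and len(records) == 1

    def test_round_trip(self, mixed_records):
        """Writing cleaned records and re-reading them is the identity."""
        records, _ = mixed_records
        frame = records_to_frame(records)
        again, report = read_records(frame)
        assert report.n_dropped == 0
        assert again == records


class TestCanonicalize:
    def test_canonical_name_maps_to_itself(self):
        assert canonicalize_name("leek", VEGETABLE_DICT) == "leek"

    @pytest.mark.parametrize("alias", ["chili", "Capsicum", "  HOT   pepper "])
    def test_aliases_collapse_to_one_category(self, alias):
        assert canonicalize_name(alias, VEGETABLE_DICT) == "pepper"

    def test_unknown_name_is_unmapped(self):
        assert canonicalize_name("starfruit", VEGETABLE_DICT) is UNMAPPED

    @given(st.sampled_from(sorted(set(VEGETABLE_DICT) | set(PESTICIDE_DICT))))
    @settings(derandomize=True, max_examples=50)
    def test_idempotent(self, raw):
        for d in (VEGETABLE_DICT, PESTICIDE_DICT):
            once = canonicalize_name(raw, d)
            if once is not UNMAPPED:
                assert canonicalize_name(once, d) == once


class TestNormalizeConcentration:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [(0.5, "mg/kg", 0.5), (500, "µg/kg", 0.5), (500, "ug/kg", 0.5),
         (2, "ppm", 2.0), (30, "ppb", 0.03)],
    )
    def test_supported_dialects(self, value, unit, expected):
        assert normalize_concentration(value, unit) == pytest.approx(expected)

    def test_unsupported_unit_signals(self):
        with pytest.raises(ValueError, match="unsupported"):
            normalize_concentration(1.0, "oz/gal")


class TestMatchMRL:
    def test_binding_kinds(self, small_mrl_table):
        rec = InspectionRecord(
            "b", "Jiangsu", "celery", 2021,
            (
                ResidueMeasurement("imidacloprid", 0.2),   # has a limit
                ResidueMeasurement("chlorpyrifos", 0.05),  # banned, no MRL
                ResidueMeasurement("abamectin", 0.01),     # absent from table
            ),
        )
        kinds = [b.kind for b in match_mrl(rec, small_mrl_table)]
        assert kinds == [LIMIT, BANNED, NO_LIMIT]

    def test_limit_binding_carries_entry(self, small_mrl_table):
        rec = InspectionRecord(
            "b", "Jiangsu", "leek", 2021, (ResidueMeasurement("procymidone", 1.0),)
        )
        (binding,) = match_mrl(rec, small_mrl_table)
        assert binding.entry.mrl == pytest.approx(0.2)

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError):
            MRLEntry("celery", "imidacloprid", mrl=0.0)
        with pytest.raises(ValueError):
            MRLEntry("celery", "imidacloprid", mrl=None, banned=False)


# conservation on randomized inputs -------------------------------------------

_row = st.tuples(
    st.sampled_from(["Jiangsu", "Yunnan", "Atlantis", ""]),
    st.sampled_from(["celery", "leek", "chili", "starfruit"]),
    st.sampled_from(["2021", "2023", "1999", "n/a"]),
    st.sampled_from(["b1", "b2", "b3", "b4", "b5"]),
    st.sampled_from(["imidacloprid", "procymidone", "mystery-x", ""]),
    st.sampled_from(["0.1", "2.5", "-1", "abc", ""]),
    st.sampled_from(["mg/kg", "µg/kg", "ppm", "oz/lb"]),
)


@given(st.lists(_row, max_size=30))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_cleaning_report_conservation(rows):
    """n_read == n_kept + all drop counts on arbitrary messy input."""
    df = pd.DataFrame(rows, columns=COLS)
    try:
        _records, report = read_records(df)
    except DataError:
        return  # conflicting duplicate batch ids are fatal by contract
    assert report.n_read == len(df)
    assert report.n_read == report.n_kept + report.n_dropped
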