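"""Ingest, per-plate DMSO normalisation and two-stage replicate averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from blisscreen.ingest_normalize import (
    PlateControlError,
    SchemaError,
    aggregate,
    apply_exclusions,
    normalize_plates,
    read_screen_table,
    write_effect_tables,
)
from conftest import make_well, well_table

TOY_TSV = """plate_id\twell\tcell_line\tdrug_a\tconc_a\tdrug_b\tconc_b\tkind\ttech_rep\tbio_rep\treadout_kind\traw_value
P1\tA1\tCL1\t\t\t\t\tvehicle_control\t1\t1\tviability\t1000
P1\tA2\tCL1\tAA\t10\t\t\tsingle\t1\t1\tviability\t640
P1\tA3\tCL1\tAA\t10\tBB\t10\tcombination\t1\t1\tviability\tNA
P1\tA4\tCL1\tBB\t10\t\t\tsingle\t1\t1\tviability\toops
"""


class TestReadScreenTable:
    def test_reads_rows_and_missing_values(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text(TOY_TSV)
        wells = read_screen_table(path)
        assert len(wells) == 4
        assert np.isnan(wells.loc[2, "raw_value"])  # literal NA
        assert np.isnan(wells.loc[3, "raw_value"])  # unparseable cell
        assert wells.loc[1, "raw_value"] == 640

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("plate_id\twell\nP1\tA1\n")
        with pytest.raises(SchemaError, match="conc_a"):
            read_screen_table(path)

    def test_schema_map_renames_foreign_headers(self, tmp_path):
        path = tmp_path / "foreign.csv"
        path.write_text(
            TOY_TSV.replace("\t", ",").replace("raw_value", "lum_counts")
        )
        wells = read_screen_table(path, schema={"lum_counts": "raw_value"})
        assert len(wells) == 4

    def test_exclusion_list_drops_wells(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text(TOY_TSV)
        wells = read_screen_table(path)
        excl = pd.DataFrame(
            {"plate_id": ["P1"], "well": ["A2"], "reason": ["bad mixing"]}
        )
        kept = apply_exclusions(wells, excl)
        assert len(kept) == 3
        assert "A2" not in set(kept["well"])


class TestNormalizePlates:
    def test_treated_well_relative_to_control_mean(self, toy_plate):
        points = normalize_plates(toy_plate)
        single = points[points["kind"] == "single"]["relative_effect"]
        assert single.iloc[0] == pytest.approx(0.5)

    def test_control_wells_self_normalise_to_mean_one(self, toy_plate):
        points = normalize_plates(toy_plate)
        ctrl = points[points["kind"] == "vehicle_control"]["relative_effect"]
        assert ctrl.mean() == pytest.approx(1.0, abs=1e-12)

    def test_growth_above_control_allowed(self):
        wells = well_table(
            [
                make_well(raw_value=900.0),
                make_well(raw_value=1100.0),
                make_well(drug_a="AA", conc_a=1.0, kind="single", raw_value=1500.0),
            ]
        )
        points = normalize_plates(wells)
        assert points[points["kind"] == "single"]["relative_effect"].iloc[0] == pytest.approx(1.5)

    def test_plate_without_controls_rejected_by_name(self):
        wells = well_table(
            [make_well(plate_id="P9", drug_a="AA", conc_a=1.0, kind="single")]
        )
        with pytest.raises(PlateControlError, match="P9"):
            normalize_plates(wells)

    def test_missing_raw_stays_missing(self, toy_plate):
        toy_plate.loc[3, "raw_value"] = np.nan
        points = normalize_plates(toy_plate)
        assert points["relative_effect"].isna().sum() == 1

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        plate = well_table(
            [
                make_well(raw_value=900.0),
                make_well(raw_value=1100.0),
                make_well(drug_a="AA", conc_a=10.0, kind="single", raw_value=640.0),
                make_well(
                    drug_a="AA", conc_a=10.0, drug_b="BB", conc_b=10.0,
                    kind="combination", raw_value=310.0,
                ),
            ]
        )
        base = normalize_plates(plate)["relative_effect"]
        rescaled = normalize_plates(
            plate.assign(raw_value=plate["raw_value"] * k)
        )["relative_effect"]
        assert np.allclose(base, rescaled, rtol=1e-9)

    def test_median_control_statistic_option(self):
        wells = well_table(
            [
                make_well(raw_value=800.0),
                make_well(raw_value=1000.0),
                make_well(raw_value=4000.0),
                make_well(drug_a="AA", conc_a=1.0, kind="single", raw_value=500.0),
            ]
        )
        med = normalize_plates(wells, control_stat="median")
        assert med[med["kind"] == "single"]["relative_effect"].iloc[0] == pytest.approx(0.5)


def _points(values_by_rep):
    """values_by_rep: {bio_rep: [tech values]} for one single-drug condition."""
    rows = []
    for b, vals in values_by_rep.items():
        for t, v in enumerate(vals, 1):
            rows.append(
                make_well(
                    plate_id=f"P{b}", drug_a="AA", conc_a=1.0, kind="single",
                    tech_rep=t, bio_rep=b, raw_value=np.nan,
                )
            )
            rows[-1]["relative_effect"] = v
    return well_table(rows)


class TestAggregate:
    def test_mean_skips_missing(self):
        agg = aggregate(_points({1: [0.5, np.nan, 0.7]}), "technical_mean")
        assert agg["mean"].iloc[0] == pytest.approx(0.6)
        assert agg["n"].iloc[0] == 2

    def test_single_value_has_no_sd(self):
        agg = aggregate(_points({1: [0.4]}), "technical_mean")
        assert agg["mean"].iloc[0] == pytest.approx(0.4)
        assert np.isnan(agg["sd"].iloc[0])
        assert agg["n"].iloc[0] == 1

    def test_sample_sd_hand_value(self):
        agg = aggregate(_points({1: [0.2], 2: [0.4], 3: [0.6]}), "biological_mean")
        assert agg["mean"].iloc[0] == pytest.approx(0.4)
        assert agg["sd"].iloc[0] == pytest.approx(0.2)

    def test_all_missing_condition_keeps_row_with_n_zero(self):
        agg = aggregate(_points({1: [np.nan, np.nan]}), "technical_mean")
        assert agg["n"].iloc[0] == 0
        assert np.isnan(agg["mean"].iloc[0])

    def test_biological_mean_is_mean_of_technical_means(self):
        # unbalanced tech counts: pooled mean would be (0.2+0.4+0.9)/3 = 0.5
        pts = _points({1: [0.2, 0.4], 2: [0.9]})
        agg = aggregate(pts, "biological_mean")
        assert agg["mean"].iloc[0] == pytest.approx((0.3 + 0.9) / 2)


class TestWriteEffectTables:
    def test_round_trip(self, tmp_path, noiseless_null_screen):
        points = normalize_plates(noiseless_null_screen)
        agg = aggregate(points, "biological_mean")
        paths = write_effect_tables(agg, tmp_path)
        assert len(paths) == 2  # one per cell line
        back = pd.read_csv(paths[0], sep="\t", na_values=["NA"])
        cell_line = back["cell_line"].iloc[0]
        orig = agg[agg["cell_line"] == cell_line]
        merged = back.merge(
            orig,
            on=["cell_line", "kind", "drug_a", "conc_a", "drug_b", "conc_b"],
            suffixes=("_r", "_o"),
        )
        ok = merged["mean_o"].notna()
        assert np.allclose(merged.loc[ok, "mean_r"], merged.loc[ok, "mean_o"], rtol=1e-4)

    def test_empty_aggregate_writes_nothing(self, tmp_path):
        assert write_effect_tables(pd.DataFrame(), tmp_path) == []
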