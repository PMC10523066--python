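import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oracles import brute_force_max_gcd_km

from paleocmr.occurrences import (
    apply_study_filters,
    build_capture_histories,
    build_stage_ranges,
    elevate_subgenera,
    max_great_circle_km,
    occurrences_from_frame,
    prepare_class_histories,
    read_occurrences,
    standardize,
)
from paleocmr.timescale import make_toy_table


def _occ_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "genus",
            "subgenus",
            "class",
            "early_interval",
            "late_interval",
            "lng",
            "lat",
            "paleolng",
            "paleolat",
        ],
    )


@pytest.fixture()
def toy_table():
    return make_toy_table(8, mass_extinction_indices=(4,))


class TestReader:
    def test_stage_resolution(self, toy_table, tmp_path):
        df = _occ_frame(
            [
                ("Aus", "", "C1", "S3", "S3", 10, 10, 9, 9),
                ("Aus", "", "C1", "S3", "", 11, 10, 10, 9),  # blank late = early
                ("Bus", "", "C1", "Permian", "Permian", 0, 0, 0, 0),
            ]
        )
        p = tmp_path / "occ.csv"
        df.to_csv(p, index=False)
        rec = read_occurrences(p, toy_table)
        assert list(rec["stage_name"]) == ["S3", "S3", ""]
        assert rec["stage_index"].tolist()[:2] == [3, 3]

    def test_unmapped_required_column_errors(self, toy_table, tmp_path):
        p = tmp_path / "occ.csv"
        pd.DataFrame({"taxon": ["A"], "early_interval": ["S1"]}).to_csv(
            p, index=False
        )
        with pytest.raises(ValueError, match="genus"):
            read_occurrences(p, toy_table)

    def test_out_of_range_coordinates_rejected(self, toy_table):
        df = _occ_frame([("Aus", "", "C1", "S1", "S1", 500, 10, 0, 0)])
        with pytest.raises(ValueError, match="coordinates"):
            occurrences_from_frame(df, toy_table)

    def test_custom_column_map(self, toy_table):
        df = _occ_frame([("Aus", "", "C1", "S1", "S1", 1, 2, 1, 2)]).rename(
            columns={"genus": "genus_name"}
        )
        rec = occurrences_from_frame(
            df, toy_table, column_map={"genus": "genus_name"}
        )
        assert rec["genus"].tolist() == ["Aus"]


class TestSubgenera:
    @pytest.mark.parametrize(
        "name,sub,expected",
        [
            ("Acila (Truncacila)", "", "Truncacila"),
            ("Acila", "", "Acila"),
            ("Acila", "Truncacila", "Truncacila"),
        ],
    )
    def test_elevation(self, toy_table, name, sub, expected):
        df = occurrences_from_frame(
            _occ_frame([(name, sub, "C1", "S1", "S1", 0, 0, 0, 0)]), toy_table
        )
        assert elevate_subgenera(df)["genus"].tolist() == [expected]

    def test_merging_is_allowed(self, toy_table):
        df = occurrences_from_frame(
            _occ_frame(
                [
                    ("Aus (Cus)", "", "C1", "S1", "S1", 0, 0, 0, 0),
                    ("Cus", "", "C1", "S2", "S2", 0, 0, 0, 0),
                ]
            ),
            toy_table,
        )
        out = elevate_subgenera(df)
        assert out["genus"].nunique() == 1


class TestFilters:
    @pytest.fixture()
    def records(self, toy_table):
        rows = [
            ("Aus", "", "C1", "S1", "S1", 0, 0, 0, 0),
            ("Aus", "", "C1", "Permian", "Permian", 0, 0, 0, 0),  # unresolved
            ("Bus", "", "C1", "S2", "S2", 0, 0, 0, 0),  # no trait
            ("Cus", "", "C1", "Cambrian Stage 4", "Cambrian Stage 4", 0, 0, 0, 0),
            ("Cus", "", "C1", "S5", "S5", 0, 0, 0, 0),
            ("Dus", "", "C2", "S3", "S3", 0, 0, 0, 0),  # class below threshold
        ]
        return occurrences_from_frame(_occ_frame(rows), toy_table)

    @pytest.fixture()
    def traits(self):
        return pd.DataFrame(
            {
                "genus": ["Aus", "Cus", "Dus"],
                "class_name": ["C1", "C1", "C2"],
                "log_size": [1.0, 2.0, 3.0],
            }
        )

    def test_rules(self, records, traits, toy_table):
        out = apply_study_filters(records, traits, toy_table, min_genera=2)
        # Bus: no trait; unresolved and pre-window occurrences dropped;
        # C2 has only 1 genus and falls below min_genera=2
        assert sorted(out["genus"].unique()) == ["Aus", "Cus"]
        assert out["stage_index"].notna().all()
        # Cus keeps its in-window occurrence even though the older one fell
        assert (out["genus"] == "Cus").sum() == 1

    def test_order_independence(self, records, traits, toy_table, rng):
        base = apply_study_filters(records, traits, toy_table, min_genera=2)
        shuffled = records.sample(frac=1, random_state=7)
        out = apply_study_filters(shuffled, traits, toy_table, min_genera=2)
        key = ["genus", "class_name", "stage_index"]
        pd.testing.assert_frame_equal(
            base.sort_values(key).reset_index(drop=True)[key],
            out.sort_values(key).reset_index(drop=True)[key],
        )

    def test_empty_result_raises(self, records, toy_table):
        no_traits = pd.DataFrame(
            {"genus": [], "class_name": [], "log_size": []}
        )
        with pytest.raises(ValueError, match="min_genera"):
            apply_study_filters(records, no_traits, toy_table, min_genera=2)


class TestGreatCircle:
    def test_antipodal_closed_form(self):
        d = max_great_circle_km(np.array([[0.0, 0.0], [180.0, 0.0]]))
        assert d == pytest.approx(np.pi * 6371.0, abs=0.1)  # 20015.1 km

    def test_one_degree_meridian(self):
        d = max_great_circle_km(np.array([[0.0, 0.0], [0.0, 1.0]]))
        assert d == pytest.approx(6371.0 * np.pi / 180.0, rel=1e-9)  # 111.19

    def test_fewer_than_two_distinct_is_an_error(self):
        with pytest.raises(ValueError, match="distinct"):
            max_great_circle_km(np.array([[1.0, 2.0], [1.0, 2.0]]))

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.column_stack(
            [rng.uniform(-180, 180, 5), rng.uniform(-90, 90, 5)]
        )
        got = max_great_circle_km(pts)
        want = brute_force_max_gcd_km(pts)
        assert got == pytest.approx(want, rel=1e-9)


class TestStageRanges:
    def test_span_filling_and_one_km_rule(self, toy_table):
        rows = [
            ("Aus", "", "C1", "S3", "S3", 0.0, 0.0, 0.0, 0.0),
            ("Aus", "", "C1", "S3", "S3", 0.0, 1.0, 0.0, 1.0),
            ("Aus", "", "C1", "S6", "S6", 5.0, 5.0, 5.0, 5.0),
        ]
        rec = occurrences_from_frame(_occ_frame(rows), toy_table)
        ranges = build_stage_ranges(rec, toy_table)
        assert ranges["stage_index"].tolist() == [3, 4, 5, 6]
        # S3: two points 1 degree apart on the meridian
        assert ranges.iloc[0]["gcd_km"] == pytest.approx(111.19, abs=0.01)
        # gap stages and the single-occurrence stage get 1 km, log range 0
        assert ranges.iloc[1:]["gcd_km"].tolist() == [1.0, 1.0, 1.0]
        assert ranges.iloc[1:]["log_range"].tolist() == [0.0, 0.0, 0.0]

    def test_all_duplicate_coordinates_get_one_km(self, toy_table):
        rows = [
            ("Aus", "", "C1", "S2", "S2", 3.0, 4.0, 3.0, 4.0),
            ("Aus", "", "C1", "S2", "S2", 3.0, 4.0, 3.0, 4.0),
        ]
        rec = occurrences_from_frame(_occ_frame(rows), toy_table)
        ranges = build_stage_ranges(rec, toy_table)
        assert ranges["gcd_km"].tolist() == [1.0]

    def test_modern_coordinate_fallback(self, toy_table):
        df = _occ_frame(
            [
                ("Aus", "", "C1", "S2", "S2", 0.0, 0.0, None, None),
                ("Aus", "", "C1", "S2", "S2", 0.0, 1.0, None, None),
            ]
        )
        rec = occurrences_from_frame(df, toy_table)
        ranges = build_stage_ranges(rec, toy_table, coord_mode="paleo")
        assert ranges["gcd_km"].iloc[0] == pytest.approx(111.19, abs=0.01)


class TestStandardize:
    def test_closed_form_z(self):
        traits = pd.DataFrame(
            {"genus": list("abc"), "class_name": "C", "log_size": [1.0, 2.0, 3.0]}
        )
        ranges = pd.DataFrame(
            {
                "class_name": "C",
                "genus": list("abc"),
                "stage_index": 1,
                "n_occ": 2,
                "gcd_km": [10.0, 100.0, 1000.0],
                "log_range": [1.0, 2.0, 3.0],
            }
        )
        t, r = standardize(traits, ranges)
        assert t["z_size"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert r["z_range"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_single_row_cell_gets_zero(self):
        traits = pd.DataFrame(
            {"genus": ["a"], "class_name": "C", "log_size": [1.0]}
        )
        ranges = pd.DataFrame(
            {
                "class_name": "C",
                "genus": ["a"],
                "stage_index": [1],
                "n_occ": [1],
                "gcd_km": [1.0],
                "log_range": [0.0],
            }
        )
        _, r = standardize(traits, ranges)
        assert r["z_range"].tolist() == [0.0]

    def test_cells_are_standard_and_invertible(self, small_histories, rng):
        _, truth, cfg = small_histories
        from paleocmr.simulate import simulate
        from paleocmr.occurrences import occurrences_from_frame

        occ, traits, _ = simulate(cfg)
        rec = occurrences_from_frame(occ, cfg.stage_table)
        traits = traits.rename(
            columns={"log10_volume_mm3": "log_size", "class": "class_name"}
        )
        ranges = build_stage_ranges(rec, cfg.stage_table)
        _, z = standardize(traits, ranges)
        for (_, _), grp in z.groupby(["class_name", "stage_index"]):
            if grp["log_range"].std(ddof=1) > 0:
                assert grp["z_range"].mean() == pytest.approx(0.0, abs=1e-9)
                assert grp["z_range"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
                # bijection: un-standardizing recovers log range
                back = (
                    grp["z_range"] * grp["log_range"].std(ddof=1)
                    + grp["log_range"].mean()
                )
                assert np.allclose(back, grp["log_range"], atol=1e-9)


class TestCaptureHistories:
    def test_detection_encoding_and_window(self, toy_table):
        rows = [
            ("Aus", "", "C1", "S3", "S3", 0.0, 0.0, 0.0, 0.0),
            ("Aus", "", "C1", "S6", "S6", 5.0, 5.0, 5.0, 5.0),
            ("Bus", "", "C1", "S2", "S2", 1.0, 1.0, 1.0, 1.0),
        ]
        rec = occurrences_from_frame(_occ_frame(rows), toy_table)
        traits = pd.DataFrame(
            {
                "genus": ["Aus", "Bus"],
                "class_name": ["C1", "C1"],
                "log_size": [1.0, 2.0],
            }
        )
        ranges = build_stage_ranges(rec, toy_table)
        traits, ranges = standardize(traits, ranges)

        full = build_capture_histories(
            rec, traits, ranges, toy_table, per_class_window=False
        )["C1"]
        assert full.n_occasions == 8
        i = full.genera.index("Aus")
        assert "".join(map(str, full.detections[i])) == "00100100"

        windowed = build_capture_histories(
            rec, traits, ranges, toy_table, per_class_window=True
        )["C1"]
        assert windowed.n_occasions == 5  # class occupies S2..S6
        assert windowed.window_start == 2

    def test_covariate_defined_at_every_occasion(self, tiny_bundle):
        cfg = tiny_bundle["config"]
        rec = occurrences_from_frame(tiny_bundle["occ"], cfg.stage_table)
        bundle = prepare_class_histories(
            rec, tiny_bundle["traits"], cfg.stage_table, min_genera=1
        )
        hist = next(iter(bundle.values()))
        assert np.all(np.isfinite(hist.z_range))
        assert np.all(np.isfinite(hist.z_size))
        assert (hist.detections.sum(axis=1) >= 1).all()

    def test_roundtrip_keeps_every_simulated_detection(self, tiny_bundle):
        """The emitted table round-trips with zero records lost and one
        history per simulated genus with at least one sampled stage."""
        cfg = tiny_bundle["config"]
        truth = tiny_bundle["truth"]
        rec = occurrences_from_frame(tiny_bundle["occ"], cfg.stage_table)
        bundle = prepare_class_histories(
            rec, tiny_bundle["traits"], cfg.stage_table, min_genera=1
        )
        hist = next(iter(bundle.values()))
        expected = int((truth.detected.sum(axis=1) >= 1).sum())
        assert hist.n_genera == expected
        got = hist.detections.sum()
        assert got == truth.detected.sum()

    def test_pipeline_is_deterministic(self, tiny_bundle):
        cfg = tiny_bundle["config"]
        outs = []
        for _ in range(2):
            rec = occurrences_from_frame(tiny_bundle["occ"], cfg.stage_table)
            bundle = prepare_class_histories(
                rec, tiny_bundle["traits"], cfg.stage_table, min_genera=1
            )
            hist = next(iter(bundle.values()))
            buf = io.StringIO()
            pd.DataFrame(hist.z_range, index=hist.genera).to_csv(buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]
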