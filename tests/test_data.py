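"""Domain types, transformations, CSV round trips and descriptives."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panthoot import study_tables
from panthoot.data import (
    MEASUREMENT_COLUMNS,
    SchemaError,
    TableParseError,
    apply_transform,
    inverse_transform,
    period_from_date,
    read_call_table,
    read_focal_table,
    standardize_rank,
    summarize_observation,
    write_call_table,
    write_focal_table,
)


class TestStandardizeRank:
    @pytest.mark.parametrize(
        "rank,n,expected",
        [(1, 5, 1.0), (5, 5, 0.0), (2, 4, 2 / 3), (3, 5, 0.5)],
    )
    def test_values(self, rank, n, expected):
        assert standardize_rank(rank, n) == pytest.approx(expected, abs=1e-12)

    def test_flipped_convention(self):
        assert standardize_rank(1, 5, alpha_high=False) == 0.0

    @given(st.integers(2, 30))
    @settings(deadline=None)
    def test_image_is_even_grid(self, n):
        # ranks 1..n map exactly onto {0, 1/(n-1), ..., 1}, decreasing
        vals = [standardize_rank(r, n) for r in range(1, n + 1)]
        grid = [(n - r) / (n - 1) for r in range(1, n + 1)]
        assert vals == grid
        assert vals[0] == 1.0 and vals[-1] == 0.0
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("rank,n", [(0, 5), (6, 5), (1, 1)])
    def test_domain_errors(self, rank, n):
        with pytest.raises(ValueError):
            standardize_rank(rank, n)


class TestTransforms:
    @pytest.mark.parametrize(
        "value,transform,expected",
        [
            (4.0, "sqrt", 2.0),
            (1.0, "log", 0.0),
            (0.1, "log_x1000", math.log(100.0)),
            (3.7, "none", 3.7),
        ],
    )
    def test_values(self, value, transform, expected):
        assert apply_transform(value, transform) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("transform", ["log", "log_x1000"])
    def test_log_rejects_nonpositive(self, transform):
        with pytest.raises(ValueError):
            apply_transform(0.0, transform)

    def test_sqrt_rejects_negative(self):
        with pytest.raises(ValueError):
            apply_transform(-1.0, "sqrt")

    @given(
        st.floats(1e-3, 1e3),
        st.sampled_from(["none", "sqrt", "log", "log_x1000"]),
    )
    @settings(deadline=None)
    def test_inverse_round_trip(self, value, transform):
        t = apply_transform(value, transform)
        assert inverse_transform(t, transform) == pytest.approx(value, rel=1e-9)


@pytest.mark.parametrize(
    "date,period",
    [
        ("2011-08-01", "before"),
        ("2011-10-15", "before"),
        ("2011-10-16", "during"),
        ("2011-11-19", "during"),
        ("2011-11-20", "after"),
        ("2012-03-01", "after"),
    ],
)
def test_period_boundaries_are_fight_and_concession(date, period):
    assert period_from_date(date) == period


class TestCallTableIO:
    def test_round_trip_identity(self, default_calls, tmp_path):
        path = tmp_path / "calls.csv"
        write_call_table(default_calls, path)
        back = read_call_table(path)
        pd.testing.assert_frame_equal(
            back.drop(columns=["date"]),
            default_calls.drop(columns=["date"]).reset_index(drop=True),
            check_dtype=False,
        )
        assert (back["date"].dt.date == default_calls["date"].dt.date).all()

    def test_empty_data_section(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "caller_id,period,rank_std,leaf_clip,complete_recording\n"
        )
        assert len(read_call_table(path)) == 0

    def test_missing_cell_becomes_nan(self, tmp_path):
        path = tmp_path / "calls.csv"
        path.write_text(
            "caller_id,period,rank_std,leaf_clip,complete_recording,intro_last_call_f0_hz\n"
            "Kuba,before,1,0,1,450\n"
            "Kuba,during,1,1,1,\n"
            "Utan,before,0.5,0,0,430\n"
        )
        df = read_call_table(path)
        assert len(df) == 3
        assert df["intro_last_call_f0_hz"].isna().tolist() == [False, True, False]

    def test_column_map_renames(self, tmp_path):
        path = tmp_path / "deposited.csv"
        path.write_text(
            "Male,Phase,StdRank,LeafClip,Complete\n"
            "Kuba,before,1.0,yes,no\n"
        )
        df = read_call_table(
            path,
            column_map={
                "Male": "caller_id",
                "Phase": "period",
                "StdRank": "rank_std",
                "LeafClip": "leaf_clip",
                "Complete": "complete_recording",
            },
        )
        assert df.loc[0, "caller_id"] == "Kuba"
        assert bool(df.loc[0, "leaf_clip"]) and not bool(df.loc[0, "complete_recording"])

    def test_unmappable_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("caller_id,rank_std,leaf_clip\nKuba,1,0\n")
        with pytest.raises(SchemaError):
            read_call_table(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "caller_id,period,rank_std,leaf_clip,complete_recording,total_duration_s\n"
            "Kuba,before,1,0,1,12.3\n"
            "Kuba,before,1,0,1,oops\n"
        )
        with pytest.raises(TableParseError) as err:
            read_call_table(path)
        assert err.value.row == 1

    def test_period_derived_from_date_when_absent(self, tmp_path):
        path = tmp_path / "dated.csv"
        path.write_text(
            "caller_id,date,rank_std,leaf_clip,complete_recording\n"
            "Kuba,2011-11-01,1,0,1\n"
        )
        assert read_call_table(path).loc[0, "period"] == "during"


class TestFocalTableIO:
    def test_round_trip(self, default_days, tmp_path):
        path = tmp_path / "days.csv"
        write_focal_table(default_days, path)
        back = read_focal_table(path)
        pd.testing.assert_frame_equal(
            back.drop(columns=["date"]),
            default_days.drop(columns=["date"]).reset_index(drop=True),
            check_dtype=False,
        )

    def test_nonpositive_hours_rejected(self, tmp_path):
        path = tmp_path / "days.csv"
        path.write_text(
            "focal_id,period,rank_std,hours_observed,n_pant_hoots,n_aggression,leaf_clip_day\n"
            "Kuba,before,1,0,3,1,0\n"
        )
        with pytest.raises(ValueError):
            read_focal_table(path)


class TestDescriptives:
    def test_study_totals(self):
        """The published focal-follow table sums to 666 h over 68 days."""
        hours = study_tables.FOCAL_HOURS.sum().sum()
        assert hours == 666.0
        days = pd.DataFrame(
            {
                "hours_observed": np.full(
                    study_tables.N_FOCAL_DAYS, hours / study_tables.N_FOCAL_DAYS
                )
            }
        )
        summary = summarize_observation(days, study_tables.reconstructed_leafclip_log())
        assert summary.total_hours == pytest.approx(666.0)
        assert summary.n_focal_days == 68
        assert summary.mean_day_hours == pytest.approx(9.79, abs=0.005)
        assert summary.n_leafclips == 36
        assert summary.n_leafclip_before_panthoot == 33
        assert summary.n_leafclip_recorded == 27
        assert summary.pct_audience_present == 86

    def test_leafclip_recording_columns_sum_to_27(self):
        assert study_tables.LEAFCLIP_RECORDINGS_PER_PERIOD.to_numpy().sum() == 27
        assert study_tables.RECORDINGS_PER_PERIOD.to_numpy().sum() == 212

    def test_single_quiet_day(self):
        days = pd.DataFrame({"hours_observed": [10.0]})
        s = summarize_observation(days, None)
        assert s.total_hours == 10.0 and s.mean_day_hours == 10.0
        assert s.n_leafclips == 0 and s.pct_audience_present == 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_observation(pd.DataFrame({"hours_observed": []}), None)

    def test_row_permutation_invariance(self, default_days, rng):
        a = summarize_observation(default_days, None)
        shuffled = default_days.sample(frac=1.0, random_state=3)
        b = summarize_observation(shuffled, None)
        assert b.total_hours == pytest.approx(a.total_hours, rel=1e-12)
        assert b.mean_day_hours == pytest.approx(a.mean_day_hours, rel=1e-12)
        assert (b.n_focal_days, b.n_leafclips, b.pct_audience_present) == (
            a.n_focal_days, a.n_leafclips, a.pct_audience_present,
        )
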