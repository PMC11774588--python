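"""Occasion grid, interval arithmetic, file round trips and panel assembly."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import charrgrowth as cg
from charrgrowth.data_io import (
    AUGUST,
    JUNE,
    build_occasion_grid,
    season_intervals,
    write_captures,
    write_repeats,
    write_temperatures,
)


def make_captures(rows):
    """rows: (fish, cave, year, month, length[, date])"""
    occs = build_occasion_grid({(y, m) for _, _, y, m, *_ in rows})
    idx = {(o.year, o.month_tag): o.index for o in occs}
    caps = [
        cg.CaptureRecord(
            fish_id=f,
            cave_id=c,
            occasion=idx[(y, m)],
            fork_length_mm=z,
            capture_date=rest[0] if rest else None,
        )
        for f, c, y, m, z, *rest in rows
    ]
    return caps, occs


def full_temps(occs, caves, value=5.0):
    return [
        cg.TemperatureRecord(cave_id=c, year=iv.year, season=iv.season, mean_temp_C=value)
        for c in caves
        for iv in season_intervals(occs)
    ]


class TestIntervalDays:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            (dt.date(2013, 6, 16), dt.date(2013, 8, 22), 67),
            (dt.date(2013, 8, 22), dt.date(2014, 6, 16), 298),
            (dt.date(2015, 8, 22), dt.date(2016, 6, 16), 299),  # leap winter
            (dt.date(2013, 6, 16), dt.date(2013, 6, 17), 1),
        ],
    )
    def test_calendar_arithmetic(self, a, b, expect):
        assert cg.interval_days(a, b) == expect

    def test_non_positive_span_rejected(self):
        with pytest.raises(cg.DataError):
            cg.interval_days(dt.date(2013, 6, 16), dt.date(2013, 6, 16))

    @given(
        start=st.dates(dt.date(2000, 1, 1), dt.date(2030, 1, 1)),
        span=st.integers(1, 2000),
    )
    @settings(max_examples=50, deadline=None)
    def test_additivity(self, start, span):
        mid = start + dt.timedelta(days=span // 2 + 1) if span >= 2 else None
        end = start + dt.timedelta(days=span)
        if mid is not None and mid < end:
            assert cg.interval_days(start, mid) + cg.interval_days(mid, end) == span
        assert cg.interval_days(start, end) == span


class TestOccasionGrid:
    def test_seasons_alternate_and_sum_to_a_year(self):
        occs = build_occasion_grid(
            [(y, m) for y in range(2012, 2019) for m in (JUNE, AUGUST)]
        )
        ivs = season_intervals(occs)
        assert [iv.season for iv in ivs[:4]] == ["summer", "winter", "summer", "winter"]
        for summer, winter in zip(ivs[::2], ivs[1::2]):
            assert summer.n_days == 67
            assert winter.n_days in (298, 299)
            year_len = summer.n_days + winter.n_days
            assert year_len in (365, 366)
        assert all(iv.n_months == (2 if iv.season == "summer" else 10) for iv in ivs)

    def test_bad_month_tag_rejected(self):
        with pytest.raises(cg.DataError):
            cg.Occasion(0, 2013, "July")


class TestReadCaptures:
    def test_three_row_parse(self, tmp_path):
        rows = [
            ("a", "c1", 2013, JUNE, 100.0),
            ("a", "c1", 2013, AUGUST, 107.0),
            ("a", "c1", 2014, JUNE, 110.0),
        ]
        caps, occs = make_captures(rows)
        write_captures(tmp_path / "c.csv", caps, occs)
        records, grid = cg.read_captures(tmp_path / "c.csv")
        assert len(records) == 3
        assert len(grid) == 3
        assert [o.month_tag for o in grid] == [JUNE, AUGUST, JUNE]

    def test_duplicate_fish_occasion_is_an_error(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "fish_id,cave_id,year,month,fork_length_mm\n"
            "a,c1,2013,June,100\na,c1,2013,June,101\n"
        )
        with pytest.raises(cg.DataError, match="duplicate"):
            cg.read_captures(p)

    def test_out_of_window_length_names_rows(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "fish_id,cave_id,year,month,fork_length_mm\n"
            "a,c1,2013,June,100\nb,c1,2013,June,500\n"
        )
        with pytest.raises(cg.DataError, match=r"\[30.0, 300.0\]"):
            cg.read_captures(p)

    def test_unknown_month_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("fish_id,cave_id,year,month,fork_length_mm\na,c1,2013,May,100\n")
        with pytest.raises(cg.DataError, match="month"):
            cg.read_captures(p)


class TestRoundTrips:
    def test_capture_round_trip_is_field_exact(self, tmp_path, paper_small_dataset):
        panel, _, _ = paper_small_dataset
        cfg = cg.preset("paper-small")
        caps, occs, temps, reps, _ = cg.simulate_dataset(cfg, seed=3)
        write_captures(tmp_path / "c.csv", caps, occs)
        back, grid = cg.read_captures(tmp_path / "c.csv")
        assert back == caps
        assert [(o.year, o.month_tag) for o in grid] == [
            (o.year, o.month_tag) for o in occs
        ]

    def test_temperature_round_trip_preserves_missing(self, tmp_path):
        cfg = cg.preset("paper-small")
        _, _, temps, _, _ = cg.simulate_dataset(cfg, seed=3)
        write_temperatures(tmp_path / "t.csv", temps)
        assert cg.read_temperatures(tmp_path / "t.csv") == temps
        assert any(t.mean_temp_C is None for t in temps)

    def test_repeat_round_trip(self, tmp_path):
        reps = cg.simulate_repeats(n_fish=5, seed=1)
        write_repeats(tmp_path / "r.csv", reps)
        assert cg.read_repeats(tmp_path / "r.csv") == reps


class TestBuildPanel:
    def test_latent_support_spans_first_to_last_capture(self):
        rows = [
            ("a", "c1", 2013, JUNE, 100.0),
            ("a", "c1", 2014, AUGUST, 115.0),  # occasions 0 and 3
            ("b", "c1", 2013, AUGUST, 90.0),
            ("b", "c2", 2014, JUNE, 95.0),
        ]
        rows[3] = ("b", "c1", 2014, JUNE, 95.0)  # keep cave constant
        caps, occs = make_captures(rows)
        panel = cg.build_panel(caps, full_temps(occs, ["c1"]), occs)
        a = panel.fish_index("a")
        assert (panel.first[a], panel.last[a]) == (0, 3)
        # 3 transitions for fish a + 1 for fish b, regardless of interior gaps
        assert panel.n_growth_intervals() == 4

    def test_single_capture_fish_has_no_intervals(self):
        caps, occs = make_captures(
            [("a", "c1", 2013, JUNE, 100.0), ("b", "c1", 2013, AUGUST, 90.0)]
        )
        panel = cg.build_panel(caps, full_temps(occs, ["c1"]), occs)
        b = panel.fish_index("b")
        assert panel.first[b] == panel.last[b]

    def test_interval_count_identity(self, paper_small_dataset):
        panel, _, _ = paper_small_dataset
        assert panel.n_growth_intervals() == int((panel.last - panel.first).sum())

    def test_actual_dates_override_nominal_days(self):
        caps, occs = make_captures(
            [
                ("a", "c1", 2013, JUNE, 100.0, dt.date(2013, 6, 20)),
                ("a", "c1", 2013, AUGUST, 107.0, dt.date(2013, 8, 22)),
            ]
        )
        panel = cg.build_panel(caps, full_temps(occs, ["c1"]), occs)
        assert panel.days[panel.fish_index("a"), 0] == 63  # actual, not 67

    def test_missing_temperature_cells_are_flagged_for_augmentation(self):
        cfg = cg.ScenarioConfig(n_caves=20, n_occasions=17, temp_missing_fraction=0.269)
        caps, occs, temps, _, _ = cg.simulate_dataset(cfg, seed=5)
        panel = cg.build_panel(caps, temps, occs)
        n_cells = panel.n_caves * (panel.n_occasions - 1)
        assert n_cells == 320
        # binomial around 86 of 320 cells
        assert 60 <= panel.n_missing_temp <= 112

    def test_uncovered_temperature_grid_is_an_error(self):
        caps, occs = make_captures(
            [("a", "c1", 2013, JUNE, 100.0), ("a", "c1", 2013, AUGUST, 104.0)]
        )
        with pytest.raises(cg.DataError, match="temperature grid"):
            cg.build_panel(caps, [], occs)

    def test_centring_defaults_to_observed_grand_means(self):
        caps, occs = make_captures(
            [("a", "c1", 2013, JUNE, 100.0), ("a", "c1", 2013, AUGUST, 110.0)]
        )
        temps = full_temps(occs, ["c1"], value=6.0)
        panel = cg.build_panel(caps, temps, occs)
        assert panel.center_size == pytest.approx(105.0)
        assert panel.center_temp == pytest.approx(6.0)
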