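"""Curve/frame data types, interpolation, integration and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from petkin.curves import (
    CurveParseError,
    FrameSchedule,
    RegionTacSet,
    SampledCurve,
    frame_average,
    read_blood_table,
    read_parent_fraction_table,
    read_tac_table,
    write_blood_table,
    write_parent_fraction_table,
    write_tac_table,
)


class TestFrameSchedule:
    def test_default_schedule_is_22_frames_ending_at_60_min(self):
        s = FrameSchedule.default_60min()
        assert s.n_frames == 22
        assert s.starts[0] == 0.0
        assert s.ends[-1] == pytest.approx(60.0)
        # 6x10s, 4x30s, 4x60s, 1x180s, 4x300s, 3x600s
        expected_s = [10] * 6 + [30] * 4 + [60] * 4 + [180] + [300] * 4 + [600] * 3
        np.testing.assert_allclose(s.durations * 60.0, expected_s)

    @pytest.mark.parametrize("frames", [
        [(0.0, 1.0), (0.5, 2.0)],        # overlap
        [(0.0, 1.0), (1.0, 0.5)],        # end <= start
        [(1.0, 2.0), (0.5, 3.0)],        # starts not increasing
        [(-1.0, 1.0)],                   # negative start
        [],
    ])
    def test_invalid_schedules_rejected(self, frames):
        with pytest.raises(ValueError):
            FrameSchedule(tuple(frames))


class TestInterpolation:
    def test_midpoint_of_segment(self):
        c = SampledCurve([1.0, 2.0], [0.0, 10.0])
        assert c.interp(1.5) == pytest.approx(5.0)

    def test_before_first_sample_linear_from_origin(self):
        c = SampledCurve([1.0], [4.0])
        assert c.interp(0.5) == pytest.approx(2.0)

    def test_after_last_sample_constant(self):
        c = SampledCurve([1.0, 2.0], [4.0, 6.0])
        assert c.interp(5.0) == pytest.approx(6.0)

    def test_negative_time_rejected(self):
        c = SampledCurve([1.0], [4.0])
        with pytest.raises(ValueError):
            c.interp(-0.1)

    def test_exact_at_sample_points(self):
        t = np.array([0.5, 1.0, 3.0, 7.0])
        v = np.array([2.0, 1.0, 5.0, 0.5])
        c = SampledCurve(t, v)
        np.testing.assert_allclose(c.interp(t), v)

    def test_parent_fraction_anchored_at_one(self):
        c = SampledCurve([10.0], [0.5], kind="parent_fraction")
        assert c.interp(0.0) == pytest.approx(1.0)
        assert c.interp(5.0) == pytest.approx(0.75)

    @pytest.mark.parametrize("times,values", [
        ([2.0, 1.0], [1.0, 2.0]),
        ([1.0, 1.0], [1.0, 2.0]),
        ([1.0], [np.inf]),
    ])
    def test_invalid_curves_rejected(self, times, values):
        with pytest.raises(ValueError):
            SampledCurve(times, values)


class TestAuc:
    def test_constant_curve(self):
        c = SampledCurve([0.0, 10.0], [1.0, 1.0])
        assert c.auc(0.0, 10.0) == pytest.approx(10.0)

    def test_linear_ramp_triangle(self):
        c = SampledCurve([0.0, 10.0], [0.0, 10.0])
        assert c.auc(0.0, 10.0) == pytest.approx(50.0)

    def test_exponential_against_closed_form(self):
        t = np.linspace(0.0, 5.0, 2001)
        c = SampledCurve(t, np.exp(-t))
        assert c.auc(0.0, 5.0) == pytest.approx(1.0 - np.exp(-5.0), abs=1e-3)

    def test_reversed_bounds_rejected(self):
        c = SampledCurve([0.0, 10.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            c.auc(5.0, 2.0)

    @given(st.floats(0.01, 9.99))
    def test_additivity(self, t):
        rng = np.random.default_rng(7)
        times = np.linspace(0.0, 10.0, 13)
        c = SampledCurve(times, rng.uniform(0.1, 5.0, times.size))
        whole = c.auc(0.0, 10.0)
        split = c.auc(0.0, t) + c.auc(t, 10.0)
        assert split == pytest.approx(whole, rel=1e-9)


class TestFrameAverage:
    def test_constant_curve(self, schedule):
        out = frame_average(lambda t: np.full_like(t, 3.2), schedule)
        np.testing.assert_allclose(out, 3.2)

    def test_linear_curve_first_frame(self):
        sched = FrameSchedule(((0.0, 1.0),))
        out = frame_average(lambda t: t, sched)
        assert out[0] == pytest.approx(0.5)

    def test_exponential_frame_average_closed_form(self):
        sched = FrameSchedule(((0.0, 0.5),))
        out = frame_average(lambda t: np.exp(-t), sched)
        assert out[0] == pytest.approx((1 - np.exp(-0.5)) / 0.5, abs=1e-6)

    def test_midpoint_mode(self, schedule):
        out = frame_average(lambda t: t, schedule, method="midpoint")
        np.testing.assert_allclose(out, schedule.mids)


class TestFileIO:
    def _tacset(self, schedule):
        rng = np.random.default_rng(0)
        return RegionTacSet(
            schedule,
            {r: rng.uniform(0.1, 2.0, schedule.n_frames)
             for r in ("cortex", "brainstem", "cerebellum_grey")},
            subject="tg03",
            group="transgenic",
        )

    def test_tac_round_trip(self, schedule, tmp_path):
        ts = self._tacset(schedule)
        path = tmp_path / "tac.csv"
        write_tac_table(ts, path)
        back = read_tac_table(path)
        assert back.subject == "tg03" and back.group == "transgenic"
        assert back.regions == ts.regions
        for r in ts.regions:
            np.testing.assert_allclose(back[r], ts[r], rtol=1e-9)
        np.testing.assert_allclose(back.schedule.ends, schedule.ends,
                                   rtol=1e-9)

    def test_default_schedule_written_has_22_rows_last_600s(self, schedule,
                                                            tmp_path):
        path = tmp_path / "tac.csv"
        write_tac_table(self._tacset(schedule), path)
        rows = [l for l in path.read_text().splitlines()
                if l and not l.startswith("#")]
        assert len(rows) == 23  # header + 22 frames
        assert rows[-1].startswith("3000,3600")

    def test_frame_end_before_start_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "frame_start_s,frame_end_s,cortex\n0,10,1.0\n10,5,1.1\n")
        with pytest.raises(CurveParseError, match="row 2"):
            read_tac_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame_start_s,cortex\n0,1.0\n")
        with pytest.raises(CurveParseError, match="frame_end_s"):
            read_tac_table(path)

    def test_blood_round_trip_converts_seconds(self, tmp_path):
        t = np.array([0.25, 0.5, 1.0, 5.0])
        wb = SampledCurve(t, [1.0, 2.0, 1.5, 0.5], kind="whole_blood")
        pl = SampledCurve(t, [1.2, 2.4, 1.8, 0.6], kind="plasma_total")
        path = tmp_path / "blood.csv"
        write_blood_table(wb, pl, path, subject="wt01")
        wb2, pl2 = read_blood_table(path)
        np.testing.assert_allclose(wb2.times, t, rtol=1e-9)
        np.testing.assert_allclose(pl2.values, pl.values, rtol=1e-9)
        assert wb2.kind == "whole_blood" and pl2.kind == "plasma_total"

    def test_blood_non_monotone_times_rejected(self, tmp_path):
        path = tmp_path / "blood.csv"
        path.write_text("time_s,whole_blood,plasma\n10,1,1\n5,1,1\n")
        with pytest.raises(CurveParseError, match="row 2"):
            read_blood_table(path)

    def test_parent_fraction_round_trip_with_scope(self, tmp_path):
        c = SampledCurve([5.0, 30.0, 60.0], [0.8, 0.4, 0.18],
                         kind="parent_fraction")
        path = tmp_path / "pf.csv"
        write_parent_fraction_table(c, path, subject="wt01",
                                    scope="population")
        back, meta = read_parent_fraction_table(path)
        np.testing.assert_allclose(back.values, c.values, rtol=1e-9)
        assert meta["scope"] == "population"

    def test_tab_delimited_accepted(self, tmp_path):
        path = tmp_path / "blood.tsv"
        path.write_text("time_s\twhole_blood\tplasma\n30\t1.0\t1.2\n"
                        "60\t0.8\t1.0\n")
        wb, pl = read_blood_table(path)
        assert wb.times[0] == pytest.approx(0.5)


class TestRegionTacSet:
    def test_wrong_length_rejected(self, schedule):
        with pytest.raises(ValueError, match="cortex"):
            RegionTacSet(schedule, {"cortex": np.ones(5)})

    def test_unknown_group_rejected(self, schedule):
        with pytest.raises(ValueError):
            RegionTacSet(schedule,
                         {"cortex": np.ones(schedule.n_frames)},
                         group="mutant")
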