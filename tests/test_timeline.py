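"""Hourly discretization, forward fill, interval means, and sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sorpkit import timeline
from conftest import make_grid


def events(rows):
    return pd.DataFrame(rows, columns=["patient_id", "time", "channel", "value"])


def patients(stays):
    return pd.DataFrame(
        [(pid, 70.0, 0.0, s, np.nan, float(s)) for pid, s in stays.items()],
        columns=["patient_id", "weight_kg", "icu_in", "icu_out", "death_time",
                 "stay_h"],
    )


class TestHourlyDiscretize:
    def test_within_hour_mean(self):
        meas = events([("P0", 3.2, "lactate", 4.0), ("P0", 3.8, "lactate", 6.0)])
        grid = timeline.hourly_discretize(meas, patients({"P0": 6}), ["lactate"])
        assert grid.loc[("P0", 3), "lactate"] == pytest.approx(5.0)

    def test_single_value_identity(self):
        meas = events([("P0", 0.5, "mbp", 2.2)])
        grid = timeline.hourly_discretize(meas, patients({"P0": 4}), ["mbp"])
        assert grid.loc[("P0", 0), "mbp"] == pytest.approx(2.2)

    def test_unmeasured_channel_all_missing(self):
        meas = events([("P0", 0.5, "mbp", 80.0)])
        grid = timeline.hourly_discretize(meas, patients({"P0": 4}),
                                          ["mbp", "lactate"])
        assert grid["lactate"].isna().all()

    def test_boundary_measurement_goes_to_later_hour(self):
        meas = events([("P0", 2.0, "mbp", 90.0)])
        grid = timeline.hourly_discretize(meas, patients({"P0": 4}), ["mbp"])
        assert grid.loc[("P0", 2), "mbp"] == pytest.approx(90.0)
        assert np.isnan(grid.loc[("P0", 1), "mbp"])

    def test_non_numeric_value_raises(self):
        meas = events([("P0", 1.0, "mbp", "high")])
        with pytest.raises(ValueError, match="non-numeric"):
            timeline.hourly_discretize(meas, patients({"P0": 4}), ["mbp"])

    def test_unknown_channel_skipped(self, caplog):
        meas = events([("P0", 1.0, "mbp", 80.0), ("P0", 1.0, "junk", 1.0)])
        with caplog.at_level("WARNING"):
            grid = timeline.hourly_discretize(meas, patients({"P0": 4}), ["mbp"])
        assert "junk" in caplog.text
        assert list(grid.columns) == ["mbp"]


class TestForwardFill:
    def test_carry_forward(self):
        grid = make_grid({"ph": {1: 7.1, 4: 7.3, 5: np.nan}})
        filled = timeline.forward_fill(grid)["ph"]
        assert filled.loc[("P0", 2)] == pytest.approx(7.1)
        assert filled.loc[("P0", 3)] == pytest.approx(7.1)
        assert filled.loc[("P0", 5)] == pytest.approx(7.3)

    def test_no_backward_leakage(self):
        grid = make_grid({"ph": {2: 7.2, 3: np.nan}})
        filled = timeline.forward_fill(grid)["ph"]
        assert filled.loc[[("P0", 0), ("P0", 1)]].isna().all()

    def test_idempotent(self, rng):
        vals = {h: (rng.normal() if rng.random() < 0.5 else np.nan)
                for h in range(20)}
        grid = make_grid({"x": vals})
        once = timeline.forward_fill(grid)
        pd.testing.assert_frame_equal(once, timeline.forward_fill(once))

    def test_fill_confined_to_patient(self):
        idx = pd.MultiIndex.from_tuples(
            [("A", 0), ("A", 1), ("B", 0), ("B", 1)],
            names=["patient_id", "hour"])
        grid = pd.DataFrame({"x": [1.0, np.nan, np.nan, 2.0]}, index=idx)
        filled = timeline.forward_fill(grid)
        assert np.isnan(filled.loc[("B", 0), "x"])


class TestCausality:
    def test_prefix_stability(self, rng):
        """Grid values at hour h are unchanged by events after h."""
        rows = [("P0", float(t), "x", float(rng.normal()))
                for t in rng.uniform(0, 24, size=40)]
        pats = patients({"P0": 24})
        full = timeline.forward_fill(
            timeline.hourly_discretize(events(rows), pats, ["x"]))
        cut = 10
        prefix_rows = [r for r in rows if r[1] < cut]
        prefix = timeline.forward_fill(
            timeline.hourly_discretize(events(prefix_rows), pats, ["x"]))
        sel = full.index.get_level_values("hour") < cut
        pd.testing.assert_frame_equal(full.loc[sel], prefix.loc[sel])

    def test_time_shift_equivariance(self, rng):
        rows = [("P0", float(t), "x", float(v))
                for t, v in zip(rng.uniform(0, 20, 30), rng.normal(size=30))]
        k = 5
        shifted = [("P0", t + k, "x", v) for _, t, _, v in rows]
        g0 = timeline.hourly_discretize(events(rows), patients({"P0": 20}), ["x"])
        g1 = timeline.hourly_discretize(events(shifted), patients({"P0": 25}), ["x"])
        for h in range(20):
            a, b = g0.loc[("P0", h), "x"], g1.loc[("P0", h + k), "x"]
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


class TestIntervalMean:
    def test_constant_series(self):
        grid = make_grid({"mbp": {h: 90.0 for h in range(24)}})
        for name in timeline.INTERVALS:
            assert timeline.interval_mean(grid, 12, name, "P0")["mbp"] == 90.0

    def test_preonset_arithmetic(self):
        grid = make_grid({"x": {h: float(h + 1) for h in range(6)}})
        out = timeline.interval_mean(grid, 6, "preonset", "P0")
        assert out["x"] == pytest.approx(3.5)

    def test_all_missing_interval(self):
        grid = make_grid({"x": {h: np.nan for h in range(12)}})
        assert np.isnan(timeline.interval_mean(grid, 12, "look_back", "P0")["x"])

    def test_outside_stay_warns(self, caplog):
        grid = make_grid({"x": {h: 1.0 for h in range(6)}})
        with caplog.at_level("WARNING"):
            out = timeline.interval_mean(grid, 2, "look_back", "P0")
        assert np.isnan(out["x"])
        assert "outside" in caplog.text

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.one_of(st.none(), st.floats(-50, 50)),
                    min_size=12, max_size=30),
           st.integers(6, 20))
    def test_matches_bruteforce(self, vals, anchor):
        grid = make_grid({"x": {h: (np.nan if v is None else v)
                                for h, v in enumerate(vals)}})
        out = timeline.interval_mean(grid, anchor, (-6, 0), "P0")["x"]
        window = [v for h, v in enumerate(vals)
                  if anchor - 6 <= h < anchor and v is not None]
        if not window or anchor - 6 >= len(vals):
            expected = np.nan if not window else np.mean(window)
        else:
            expected = np.mean(window)
        assert (np.isnan(out) and (isinstance(expected, float) and np.isnan(expected))) \
            or out == pytest.approx(expected)


def _labels(shock_hours):
    return pd.DataFrame(
        [(pid, h) for pid, h in shock_hours.items()],
        columns=["patient_id", "t_septic_shock"])


class TestBuildSamples:
    def test_positive_anchor_and_window(self):
        grid = timeline.forward_fill(make_grid(
            {"x": {h: float(h) for h in range(40)}}))
        ss = timeline.build_samples(grid, _labels({"P0": 30.0}))
        assert len(ss.frame) == 1
        row = ss.frame.iloc[0]
        assert row["anchor_hour"] == 24
        assert row["label"] == 1
        # features = mean of filled hours 18..23
        assert row["x"] == pytest.approx(np.mean(range(18, 24)))

    def test_nonshock_patient_all_negative(self, rng):
        grid = timeline.forward_fill(make_grid(
            {"x": {h: 1.0 for h in range(30)}}))
        ss = timeline.build_samples(grid, _labels({"P0": np.nan}),
                                    sampling="all_hours")
        assert (ss.y == 0).all()

    def test_early_onset_excluded(self):
        grid = timeline.forward_fill(make_grid(
            {"x": {h: 1.0 for h in range(20)}}))
        ss = timeline.build_samples(grid, _labels({"P0": 4.0}))
        assert len(ss.frame) == 0

    def test_incomplete_lookback_dropped_and_counted(self):
        grid = make_grid({"x": {h: np.nan for h in range(40)}})
        ss = timeline.build_samples(grid, _labels({"P0": 30.0}))
        assert len(ss.frame) == 0
        assert ss.n_dropped_incomplete == 1

    def test_one_per_patient_is_seeded(self):
        grid = timeline.forward_fill(make_grid({"x": {h: 1.0 for h in range(30)}}))
        a = timeline.build_samples(grid, _labels({"P0": np.nan}),
                                   sampling="one_per_patient",
                                   rng=np.random.default_rng(3))
        b = timeline.build_samples(grid, _labels({"P0": np.nan}),
                                   sampling="one_per_patient",
                                   rng=np.random.default_rng(3))
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_unknown_policy_rejected(self):
        grid = make_grid({"x": {0: 1.0}})
        with pytest.raises(ValueError, match="policy"):
            timeline.build_samples(grid, _labels({}), sampling="bogus")
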