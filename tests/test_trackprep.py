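import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthotrack import trackprep
from benthotrack.raster import NODATA, BenthoscapeRaster
from benthotrack.trackprep import build_steps, filter_steps, resample, wrap_angle

from conftest import make_fixes


class TestWrapAngle:
    @settings(max_examples=200, deadline=None)
    @given(theta=st.floats(-50.0, 50.0))
    def test_range_and_periodicity(self, theta):
        w = float(wrap_angle(theta))
        assert -np.pi < w <= np.pi
        assert np.isclose(float(wrap_angle(theta + 2 * np.pi)), w, atol=1e-9)

    def test_pi_maps_to_pi(self):
        assert float(wrap_angle(np.pi)) == pytest.approx(np.pi)
        assert float(wrap_angle(-np.pi)) == pytest.approx(np.pi)


class TestResample:
    def test_greedy_trace(self):
        fixes = make_fixes(np.array([0, 3, 6, 9, 12, 20, 31]) * 60.0)
        kept = resample(fixes, rate=600, tolerance=120)
        t0 = pd.to_datetime(fixes["t"]).iloc[0]
        got = ((pd.to_datetime(kept["t"]) - t0).dt.total_seconds() / 60).tolist()
        assert got == [0, 9, 20, 31]
        assert kept["burst_id"].nunique() == 1

    def test_exact_rate_keeps_everything(self):
        fixes = make_fixes(np.arange(10) * 600.0)
        kept = resample(fixes)
        assert len(kept) == 10
        assert kept["burst_id"].nunique() == 1

    def test_all_gaps_too_long_gives_no_bursts(self):
        fixes = make_fixes(np.arange(5) * 1800.0)
        kept = resample(fixes)
        assert len(kept) == 0

    def test_unsorted_input_rejected(self):
        fixes = make_fixes([600.0, 0.0])
        with pytest.raises(ValueError, match="sorted"):
            resample(fixes)

    def test_burst_split_on_long_gap(self):
        t = np.concatenate([np.arange(4) * 600.0, 10000 + np.arange(4) * 600.0])
        kept = resample(make_fixes(t))
        assert kept["burst_id"].nunique() == 2

    @settings(max_examples=100, deadline=None)
    @given(
        gaps=st.lists(st.floats(30.0, 2000.0), min_size=1, max_size=60),
    )
    def test_within_burst_gaps_in_window(self, gaps):
        t = np.concatenate([[0.0], np.cumsum(gaps)])
        kept = resample(make_fixes(t), rate=600, tolerance=120)
        for _, b in kept.groupby("burst_id"):
            dt = np.diff(pd.to_datetime(b["t"]).astype("int64") / 1e9)
            assert np.all((dt >= 480 - 1e-6) & (dt <= 720 + 1e-6))
            assert len(b) >= 2


class TestBuildSteps:
    def test_right_angle_turn(self):
        fixes = make_fixes([0, 600, 1200], x=[0, 1, 1], y=[0, 0, 1])
        fixes["burst_id"] = 0
        steps = build_steps(fixes)
        assert len(steps) == 2
        assert steps["sl"].tolist() == [1.0, 1.0]
        assert np.isnan(steps["ta"].iloc[0])
        assert steps["ta"].iloc[1] == pytest.approx(np.pi / 2)
        assert steps["cos_ta"].iloc[1] == pytest.approx(0.0, abs=1e-15)

    def test_collinear_is_zero_turn(self):
        fixes = make_fixes([0, 600, 1200], x=[0, 1, 2], y=[0, 0, 0])
        fixes["burst_id"] = 0
        steps = build_steps(fixes)
        assert steps["ta"].iloc[1] == pytest.approx(0.0)
        assert steps["cos_ta"].iloc[1] == pytest.approx(1.0)

    def test_repeated_point_gives_nonfinite_log_sl(self):
        fixes = make_fixes([0, 600], x=[0, 0], y=[0, 0])
        fixes["burst_id"] = 0
        steps = build_steps(fixes)
        assert steps["sl"].iloc[0] == 0.0
        assert steps["log_sl"].iloc[0] == -np.inf

    def test_step_count_is_burst_length_minus_one(self):
        rng = np.random.default_rng(0)
        for n in [2, 5, 11]:
            fixes = make_fixes(
                np.arange(n) * 600.0, x=rng.normal(size=n), y=rng.normal(size=n)
            )
            fixes["burst_id"] = 0
            assert len(build_steps(fixes)) == n - 1


class TestFilterSteps:
    def test_zero_length_step_removed(self):
        rng = np.random.default_rng(1)
        n = 11
        x = np.cumsum(rng.normal(size=n))
        x[4] = x[3]
        y = np.cumsum(rng.normal(size=n))
        y[4] = y[3]
        fixes = make_fixes(np.arange(n) * 600.0, x=x, y=y)
        fixes["burst_id"] = 0
        steps = build_steps(fixes)
        kept, counts = filter_steps(steps)
        assert counts["infinite_log_sl"] == 1
        assert len(kept) == 10 - counts["missing_ta"] - 1

    def test_burst_of_five_has_three_computable_turns(self):
        rng = np.random.default_rng(2)
        fixes = make_fixes(
            np.arange(5) * 600.0, x=rng.normal(size=5), y=rng.normal(size=5)
        )
        fixes["burst_id"] = 0
        steps = build_steps(fixes)
        assert len(steps) == 4
        kept, counts = filter_steps(steps)
        assert len(kept) == 3
        assert counts["missing_ta"] == 1

    def test_empty_input(self):
        kept, counts = filter_steps(pd.DataFrame(columns=trackprep.STEP_COLUMNS))
        assert kept.empty
        assert counts == {"infinite_log_sl": 0, "missing_ta": 0}


class TestAttachCovariates:
    def test_uniform_raster(self, uniform_raster):
        fixes = make_fixes([0, 600], x=[5, 15], y=[5, 15])
        fixes["burst_id"] = 0
        steps = trackprep.attach_covariates(build_steps(fixes), uniform_raster)
        assert (steps["start_class"] == 4).all()
        assert (steps["end_class"] == 4).all()

    def test_boundary_crossing_uses_endpoints_only(self, small_raster):
        fixes = make_fixes([0, 600], x=[5, 15], y=[5, 15])
        fixes["burst_id"] = 0
        steps = trackprep.attach_covariates(build_steps(fixes), small_raster)
        assert steps["start_class"].iloc[0] == 0
        assert steps["end_class"].iloc[0] == 3

    def test_nodata_endpoint_kept_as_level(self):
        r = BenthoscapeRaster(0, 0, 10.0, np.array([[NODATA, 4]]))
        fixes = make_fixes([0, 600], x=[5, 15], y=[5, 5])
        fixes["burst_id"] = 0
        steps = trackprep.attach_covariates(build_steps(fixes), r)
        assert steps["start_class"].iloc[0] == NODATA

    def test_out_of_extent_errors(self, small_raster):
        fixes = make_fixes([0, 600], x=[5, 50], y=[5, 5])
        fixes["burst_id"] = 0
        with pytest.raises(Exception, match="outside raster bounds"):
            trackprep.attach_covariates(build_steps(fixes), small_raster)


class TestClipToRaster:
    def test_drops_out_of_extent_fixes(self, small_raster):
        fixes = make_fixes([0, 600, 1200], x=[5, 50, 15], y=[5, 5, 5])
        kept = trackprep.clip_to_raster(fixes, small_raster)
        assert len(kept) == 2
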