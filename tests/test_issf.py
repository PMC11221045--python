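import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from benthotrack import issf, trackprep
from benthotrack.raster import BenthoscapeRaster
from benthotrack.simulate import (
    SimulationConfig,
    generate_benthoscape,
    simulate_track,
    track_to_fixes,
)
from benthotrack.stats.distributions import (
    GammaParams,
    MovementKernel,
    VonMisesParams,
)


def true_track_steps(raster, beta, n_steps, seed, kernel=None, start=None):
    cfg = SimulationConfig()
    kernel = kernel or cfg.kernel
    xmin, ymin, xmax, ymax = raster.bounds
    start = start or ((xmin + xmax) / 2, (ymin + ymax) / 2)
    track = simulate_track(raster, kernel, beta, start, n_steps, seed=seed)
    steps = trackprep.steps_from_fixes(track_to_fixes(track), rate=600, tolerance=1)
    return trackprep.attach_covariates(steps, raster), kernel


@pytest.fixture(scope="module")
def patchy_raster():
    cfg = SimulationConfig(
        n_rows=150, n_cols=150,
        proportions={0: 0.2, 1: 0.25, 2: 0.2, 3: 0.15, 4: 0.2},
        patchiness=15.0,
    )
    return generate_benthoscape(cfg, seed=77)


class TestDrawRandomSteps:
    def test_stratum_size(self, patchy_raster):
        steps, kernel = true_track_steps(patchy_raster, {}, 300, seed=1)
        strata = issf.draw_random_steps(steps, kernel, patchy_raster, n_random=100, seed=2)
        sizes = strata.groupby("stratum").size()
        assert (sizes == 101).all()
        assert strata.groupby("stratum")["case"].sum().eq(1).all()

    def test_concentrated_kernel_gives_tight_angles(self, patchy_raster):
        steps, _ = true_track_steps(patchy_raster, {}, 200, seed=3)
        kernel = MovementKernel(GammaParams(2.0, 2.0), VonMisesParams(kappa=500.0))
        strata = issf.draw_random_steps(steps, kernel, patchy_raster, n_random=50, seed=4)
        rand = strata[~strata["case"]]
        assert np.abs(rand["ta"]).max() < 0.2

    def test_random_step_lengths_match_tentative_gamma(self, patchy_raster):
        steps, _ = true_track_steps(patchy_raster, {}, 300, seed=5)
        kernel = MovementKernel(GammaParams(2.0, 5.0), VonMisesParams(kappa=1.0))
        strata = issf.draw_random_steps(steps, kernel, patchy_raster, n_random=40, seed=6)
        rand = strata[~strata["case"]]
        sl = rand["sl"].to_numpy()[:10_000]
        p = sps.kstest(sl, sps.gamma(a=2.0, scale=5.0).cdf).pvalue
        assert p > 0.01

    def test_members_share_start(self, patchy_raster):
        steps, kernel = true_track_steps(patchy_raster, {}, 100, seed=7)
        strata = issf.draw_random_steps(steps, kernel, patchy_raster, n_random=20, seed=8)
        shared = strata.groupby("stratum")["start_class"].nunique()
        assert (shared == 1).all()


class TestBuildDesign:
    def test_column_count(self, patchy_raster):
        steps, kernel = true_track_steps(patchy_raster, {}, 400, seed=9)
        strata = issf.draw_random_steps(steps, kernel, patchy_raster, n_random=30, seed=10)
        X, y, sid, terms = issf.build_issf_design(strata)
        n_end = strata["end_class"].nunique()
        n_start = strata["start_class"].nunique()
        assert X.shape[1] == (n_end - 1) + 2 + 2 * (n_start - 1)
        assert len(terms) == X.shape[1]
        assert y.sum() == strata["stratum"].nunique()

    def test_single_stratum_constant_end_flagged_by_fit(self):
        # the case's (log_sl, cos_ta) lies inside the control hull so the
        # only degeneracy is the within-stratum-constant end class
        log_sl = np.array([0.7, 0.2, 1.2, 0.7, 0.7])
        cos_ta = np.array([0.95, 0.95, 0.95, 0.85, 0.999])
        strata = pd.DataFrame(
            {
                "stratum": 0,
                "case": [True, False, False, False, False],
                "sl": np.exp(log_sl),
                "log_sl": log_sl,
                "ta": np.arccos(cos_ta),
                "cos_ta": cos_ta,
                "start_class": 4,
                "end_class": 4,
            }
        )
        X, y, sid, terms = issf.build_issf_design(strata)
        from benthotrack.stats.clogit import fit_clogit

        fit = fit_clogit(X, y, sid, terms=terms)
        assert "end_4" in fit.dropped_terms

    def test_min_support_excludes_rare_levels(self, patchy_raster):
        steps, kernel = true_track_steps(patchy_raster, {}, 400, seed=11)
        strata = issf.draw_random_steps(steps, kernel, patchy_raster, n_random=30, seed=12)
        X0, _, _, terms0 = issf.build_issf_design(strata, min_support=0)
        X5, _, _, terms5 = issf.build_issf_design(strata, min_support=5)
        assert set(terms5) <= set(terms0)


class TestFitISSF:
    def test_recovery_of_generating_selection(self, patchy_raster):
        """Fitting tracks generated by the step-selection process
        recovers the generating coefficients."""
        beta = {2: 1.0, 0: -0.5}
        steps, kernel_true = true_track_steps(patchy_raster, beta, 2000, seed=13)
        tentative = issf.fit_tentative_kernel(steps)
        strata = issf.draw_random_steps(steps, tentative, patchy_raster, n_random=25, seed=14)
        est = issf.fit_issf(strata, B=100, seed=15)
        t = est.table()
        assert t.loc["end_2", "estimate"] == pytest.approx(1.0, abs=0.3)
        assert t.loc["end_0", "estimate"] == pytest.approx(-0.5, abs=0.3)
        # truth inside the percentile bootstrap interval
        assert t.loc["end_2", "pct_lo"] <= 1.0 <= t.loc["end_2", "pct_hi"]

    def test_null_estimates_near_zero(self, patchy_raster):
        steps, kernel = true_track_steps(patchy_raster, {}, 2000, seed=16)
        tentative = issf.fit_tentative_kernel(steps)
        strata = issf.draw_random_steps(steps, tentative, patchy_raster, n_random=25, seed=17)
        est = issf.fit_issf(strata, B=50, seed=18)
        t = est.table()
        for term in t.index:
            if term.startswith("end_"):
                assert abs(t.loc[term, "estimate"]) < 0.2

    def test_determinism(self, patchy_raster):
        steps, kernel = true_track_steps(patchy_raster, {}, 300, seed=19)
        tentative = issf.fit_tentative_kernel(steps)
        strata = issf.draw_random_steps(steps, tentative, patchy_raster, n_random=20, seed=20)
        e1 = issf.fit_issf(strata, B=40, seed=21)
        e2 = issf.fit_issf(strata, B=40, seed=21)
        np.testing.assert_array_equal(e1.bootstrap.mean, e2.bootstrap.mean)
        np.testing.assert_array_equal(e1.bootstrap.sd, e2.bootstrap.sd)

    def test_too_few_strata_refused(self, patchy_raster):
        steps, kernel = true_track_steps(patchy_raster, {}, 15, seed=22)
        tentative = MovementKernel(GammaParams(2.0, 5.0), VonMisesParams(kappa=1.0))
        strata = issf.draw_random_steps(steps, tentative, patchy_raster, n_random=10, seed=23)
        with pytest.raises(ValueError, match="minimum 20"):
            issf.fit_issf(strata, B=10, seed=24)


class TestUpdateKernel:
    def make_estimates(self, entries):
        df = pd.DataFrame({"estimate": entries})
        df.index.name = "term"
        return df

    def test_zero_coefficients_identity(self):
        tent = MovementKernel(GammaParams(2.0, 5.0), VonMisesParams(kappa=1.0))
        est = self.make_estimates(
            {"log_sl": 0.0, "cos_ta": 0.0, "start_2:log_sl": 0.0, "start_2:cos_ta": 0.0}
        )
        upd = issf.update_kernel(tent, est)
        assert upd.loc[1, "shape"] == 2.0
        assert upd.loc[1, "kappa"] == 1.0
        assert upd.loc[2, "shape"] == 2.0
        assert upd.loc[2, "kappa"] == 1.0

    def test_mixed_sediment_shape_update(self):
        # a positive start x log_sl interaction concentrates the gamma
        # shape away from 0 on that substrate
        tent = MovementKernel(GammaParams(2.0, 5.0), VonMisesParams(kappa=1.0))
        est = self.make_estimates(
            {"log_sl": 0.0, "cos_ta": 0.0, "start_2:log_sl": 0.37, "start_2:cos_ta": 0.0}
        )
        upd = issf.update_kernel(tent, est)
        assert upd.loc[2, "shape"] == pytest.approx(2.37)

    def test_mixed_sediment_kappa_update(self):
        tent = MovementKernel(GammaParams(2.0, 5.0), VonMisesParams(kappa=1.0))
        est = self.make_estimates(
            {"log_sl": 0.0, "cos_ta": 0.0, "start_2:log_sl": 0.0, "start_2:cos_ta": -0.49}
        )
        upd = issf.update_kernel(tent, est)
        assert upd.loc[2, "kappa"] == pytest.approx(0.51)
        assert bool(upd.loc[2, "valid"])

    def test_invalid_flagged_not_raised(self):
        tent = MovementKernel(GammaParams(0.5, 5.0), VonMisesParams(kappa=0.2))
        est = self.make_estimates({"log_sl": -1.0, "cos_ta": -1.0})
        upd = issf.update_kernel(tent, est)
        assert not bool(upd.loc[1, "valid"])


class TestInterpretEstimates:
    def make(self, entries):
        df = pd.DataFrame({"boot_mean": entries})
        df.index.name = "term"
        return df

    def test_sign_labels(self):
        est = self.make(
            {
                "end_2": 0.8,
                "end_0": -0.3,
                "end_4": 0.0,
                "log_sl": 0.1,
                "cos_ta": 0.0,
                "start_2:cos_ta": -0.49,
                "start_4:log_sl": 1.51,
            }
        )
        out = issf.interpret_estimates(est)
        assert out.loc["start_2:cos_ta", "interpretation"] == "lower directionality / more turning"
        assert out.loc["start_4:log_sl", "interpretation"] == "longer steps / more exploratory"
        assert out.loc["end_2", "interpretation"] == "selected over reference"
        assert out.loc["end_0", "interpretation"] == "avoided relative to reference"
        assert out.loc["end_4", "interpretation"] == "no difference from reference"

    def test_row_permutation_invariance(self):
        entries = {
            "end_2": 0.8, "end_0": -0.3, "start_2:cos_ta": -0.49,
            "start_4:log_sl": 1.51, "log_sl": 0.3, "cos_ta": -0.2,
        }
        est = self.make(entries)
        shuffled = est.iloc[::-1]
        out1 = issf.interpret_estimates(est).sort_index()
        out2 = issf.interpret_estimates(shuffled).sort_index()
        pd.testing.assert_frame_equal(out1, out2)
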