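import numpy as np
import pandas as pd
import pytest
import shapely

from benthotrack import rsf
from benthotrack.raster import NODATA, BenthoscapeRaster
from benthotrack.simulate import SimulationConfig, generate_benthoscape, weighted_presences


def presence_frame(x, y, tag="BL 001"):
    return pd.DataFrame({"tag_id": tag, "x_m": x, "y_m": y})


class TestDrawPseudoAbsences:
    def test_count_and_containment(self, uniform_raster):
        rng = np.random.default_rng(0)
        pres = presence_frame(rng.uniform(20, 180, 100), rng.uniform(20, 180, 100))
        data = rsf.draw_pseudo_absences(pres, uniform_raster, ratio=10, seed=1)
        absences = data[~data["case"]]
        assert len(absences) == 1000
        assert data["case"].sum() == 100
        hull = rsf.minimum_convex_polygon(pres["x_m"], pres["y_m"])
        inside = shapely.contains_xy(
            hull.buffer(1e-9), absences["x"].to_numpy(), absences["y"].to_numpy()
        )
        assert inside.all()

    def test_square_corners_containment(self, uniform_raster):
        pres = presence_frame([20, 180, 180, 20, 100], [20, 20, 180, 180, 100])
        data = rsf.draw_pseudo_absences(pres, uniform_raster, ratio=10, seed=2)
        absences = data[~data["case"]]
        assert absences["x"].between(20, 180).all()
        assert absences["y"].between(20, 180).all()

    def test_uniform_raster_single_class(self, uniform_raster):
        rng = np.random.default_rng(3)
        pres = presence_frame(rng.uniform(20, 180, 30), rng.uniform(20, 180, 30))
        data = rsf.draw_pseudo_absences(pres, uniform_raster, seed=3)
        assert (data["substrate"] == 4).all()

    def test_collinear_presences_rejected(self, uniform_raster):
        pres = presence_frame([10, 20, 30, 40, 50], [10, 20, 30, 40, 50])
        with pytest.raises(ValueError, match="zero area"):
            rsf.draw_pseudo_absences(pres, uniform_raster)

    def test_too_few_presences_rejected(self, uniform_raster):
        pres = presence_frame([10, 20, 30], [10, 25, 30])
        with pytest.raises(ValueError, match="at least 5"):
            rsf.draw_pseudo_absences(pres, uniform_raster)

    def test_nodata_kept_as_level(self):
        r = BenthoscapeRaster(0, 0, 10.0, np.full((20, 20), NODATA))
        rng = np.random.default_rng(4)
        pres = presence_frame(rng.uniform(20, 180, 20), rng.uniform(20, 180, 20))
        data = rsf.draw_pseudo_absences(pres, r, seed=4)
        assert (data["substrate"] == NODATA).all()


def build_weighted_study(seed, weights, n_individuals=4, n_presences=220, ratio=10):
    """Use-available data for individuals whose presences follow known
    selection weights over a patchy raster.

    Presences and pseudo-absences share the same explicit availability
    domain so the log selection weights are the exact estimand (an MCP
    domain only approximates the presence-sampling region and clips its
    corners, which biases the contrast when corner composition differs
    from the bulk by chance).
    """
    from shapely.geometry import box

    cfg = SimulationConfig(
        n_rows=150, n_cols=150,
        proportions={0: 0.2, 1: 0.2, 2: 0.2, 3: 0.2, 4: 0.2},
        patchiness=15.0,
    )
    raster = generate_benthoscape(cfg, seed=seed)
    margin = 5.0
    xmin, ymin, xmax, ymax = raster.bounds
    domain = box(xmin + margin, ymin + margin, xmax - margin, ymax - margin)
    frames = []
    ss = np.random.SeedSequence(seed + 1)
    for i, child in enumerate(ss.spawn(2 * n_individuals)):
        pres = weighted_presences(
            raster, weights, n_presences,
            seed=np.random.default_rng(child), tag_id=f"BL {i:03d}", margin=margin,
        )
        frames.append(
            rsf.draw_pseudo_absences(
                pres, raster, ratio=ratio, domain=domain,
                seed=np.random.default_rng(ss.spawn(1)[0]),
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestResampleFit:
    def test_known_weights_recovery(self):
        """Presences drawn with weight 3 on mixed sediments recover a
        median coefficient near ln 3 under the subsample-refit scheme."""
        data = build_weighted_study(seed=101, weights={2: 3.0}, n_presences=400)
        coefs = rsf.rsf_resample_fit(data, reruns=20, per_individual=100, seed=5)
        med = coefs["substrate_2"].median()
        assert np.log(3) - 0.25 <= med <= np.log(3) + 0.25

    def test_null_medians_near_zero(self):
        data = build_weighted_study(
            seed=103, weights={}, n_individuals=6, n_presences=500
        )
        coefs = rsf.rsf_resample_fit(data, reruns=20, per_individual=100, seed=6)
        for col in coefs.columns:
            if col.startswith("substrate_"):
                assert abs(coefs[col].median()) < 0.2

    def test_deterministic(self):
        data = build_weighted_study(seed=105, weights={0: 2.0}, n_individuals=2)
        c1 = rsf.rsf_resample_fit(data, reruns=4, per_individual=80, seed=7)
        c2 = rsf.rsf_resample_fit(data, reruns=4, per_individual=80, seed=7)
        pd.testing.assert_frame_equal(c1, c2)

    def test_individuals_without_enough_points_excluded(self, caplog):
        data = build_weighted_study(seed=107, weights={}, n_individuals=3)
        # cripple one individual
        first = data["tag_id"] == "BL 000"
        data = pd.concat([data[first].head(20), data[~first]], ignore_index=True)
        coefs = rsf.rsf_resample_fit(data, reruns=3, per_individual=100, seed=8)
        assert len(coefs) == 3

    def test_one_outcome_level_recorded_as_nan_not_crash(self):
        """A substrate never among an individual's presences would
        separate the logistic fit; its coefficient is NaN for reruns
        where the subset lacks both outcomes on that level."""
        data = build_weighted_study(seed=111, weights={}, n_individuals=2,
                                    n_presences=150)
        # force substrate 3 to appear only among pseudo-absences
        data = data[~(data["case"] & (data["substrate"] == 3))].reset_index(drop=True)
        coefs = rsf.rsf_resample_fit(data, reruns=5, per_individual=100, seed=10)
        assert coefs["substrate_3"].isna().all()
        rss = rsf.relative_selection_strength(coefs)
        assert rss.loc[3, "n_estimable"] == 0
        assert bool(rss.loc[3, "no_clear_selection"])
        # the other classes are still summarized over all reruns
        assert rss.loc[0, "n_estimable"] == 5

    def test_fewer_than_two_usable_rejected(self):
        data = build_weighted_study(seed=109, weights={}, n_individuals=2, n_presences=50)
        with pytest.raises(ValueError, match="at least 2"):
            rsf.rsf_resample_fit(data, reruns=2, per_individual=100, seed=9)


class TestRelativeSelectionStrength:
    def test_zero_coefficient_gives_rss_one(self):
        coefs = pd.DataFrame({"substrate_0": [0.0, 0.0], "substrate_2": [np.log(2)] * 2})
        rss = rsf.relative_selection_strength(coefs)
        assert rss.loc[0, "rss_median"] == pytest.approx(1.0)
        assert rss.loc[2, "rss_median"] == pytest.approx(2.0)
        assert rss.loc[1, "rss_median"] == 1.0  # reference identically 1

    def test_straddling_zero_flagged(self):
        coefs = pd.DataFrame({"substrate_0": [-0.5, -0.1, 0.2, 0.6]})
        rss = rsf.relative_selection_strength(coefs)
        assert bool(rss.loc[0, "no_clear_selection"])

    def test_one_sided_not_flagged(self):
        coefs = pd.DataFrame({"substrate_0": [0.4, 0.5, 0.9, 0.6]})
        rss = rsf.relative_selection_strength(coefs)
        assert not bool(rss.loc[0, "no_clear_selection"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rsf.relative_selection_strength(pd.DataFrame())
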