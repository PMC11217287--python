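"""Seed segmentation, shape measurement, growth formulas and cell growth."""

import warnings

import numpy as np
import pandas as pd
import pytest
from skimage.draw import ellipse as draw_ellipse

from seedmech import morphometry as morph
from seedmech import synthetic as syn


class TestGrowthFormulas:
    def test_hand_computed_case(self):
        daily = pd.DataFrame(
            {
                "mean_area": [100.0, 150.0],
                "sd_area": [10.0, 15.0],
                "mean_ar": [1.0, 1.2],
                "sd_ar": [0.1, 0.12],
            }
        )
        g = morph.growth_derivative_series(daily)
        assert g["growth_rate"].iloc[0] == 0.5
        assert g["sd_growth_rate"].iloc[0] == pytest.approx(np.sqrt(0.1**2 + 0.1**2))
        assert g["sd_growth_rate"].iloc[0] == pytest.approx(0.1414, abs=5e-5)
        assert g["growth_anisotropy"].iloc[0] == pytest.approx(0.2)

    def test_constant_series(self):
        cv = 0.07
        daily = pd.DataFrame(
            {
                "mean_area": [200.0] * 4,
                "sd_area": [200.0 * cv] * 4,
                "mean_ar": [1.5] * 4,
                "sd_ar": [1.5 * cv] * 4,
            }
        )
        g = morph.growth_derivative_series(daily)
        assert (g["growth_rate"] == 0.0).all()
        assert np.allclose(g["sd_growth_rate"], np.sqrt(2) * cv)

    def test_recovers_generator_truth(self):
        truth_area = [100.0, 150.0, 225.0]
        obs = syn.make_growth_observations(truth_area, [1.0, 1.2, 1.44], 0.1, 200, rng_seed=3)
        g = morph.growth_derivative_series(syn.summarize_growth_observations(obs))
        assert np.allclose(g["growth_rate"], 0.5, atol=0.05)
        assert np.allclose(g["growth_anisotropy"], 0.2, atol=0.05)

    def test_nonpositive_mean_rejected(self):
        daily = pd.DataFrame(
            {"mean_area": [100.0, -1.0], "sd_area": [1, 1], "mean_ar": [1, 1], "sd_ar": [0, 0]}
        )
        with pytest.raises(morph.DomainError):
            morph.growth_derivative_series(daily)

    def test_single_day_rejected(self):
        daily = pd.DataFrame(
            {"mean_area": [100.0], "sd_area": [1.0], "mean_ar": [1.0], "sd_ar": [0.1]}
        )
        with pytest.raises(morph.DomainError):
            morph.growth_derivative_series(daily)


class TestMeasureSeed:
    def _ellipse_mask(self, half_a, half_b, angle_deg=0.0, pad=30):
        size = int(2 * (half_a + pad))
        mask = np.zeros((size, size), dtype=bool)
        rr, cc = draw_ellipse(
            size // 2, size // 2, half_b, half_a, rotation=np.deg2rad(angle_deg)
        )
        mask[rr, cc] = True
        return mask

    @pytest.mark.parametrize("mode", ["ellipse", "axes"])
    def test_aspect_ratio_170_by_100(self, mode):
        mask = self._ellipse_mask(170, 100)
        shape = morph.measure_seed(mask, mode=mode)
        assert shape.aspect_ratio == pytest.approx(1.70, abs=0.02)

    def test_circle_aspect_ratio_unity(self):
        mask = self._ellipse_mask(80, 80)
        shape = morph.measure_seed(mask, mode="ellipse")
        assert shape.aspect_ratio == pytest.approx(1.00, abs=0.01)

    def test_area_matches_analytic(self):
        mask = self._ellipse_mask(170, 100)
        shape = morph.measure_seed(mask)
        assert shape.area == pytest.approx(np.pi * 170 * 100, rel=0.01)

    @pytest.mark.parametrize("angle", [0.0, 23.0, 67.0, 90.0])
    def test_rotation_invariance(self, angle):
        mask = self._ellipse_mask(120, 70, angle_deg=angle)
        shape = morph.measure_seed(mask, mode="ellipse")
        assert shape.aspect_ratio == pytest.approx(120 / 70, rel=0.01)

    def test_scale_invariance_of_aspect(self):
        small = morph.measure_seed(self._ellipse_mask(60, 40))
        large = morph.measure_seed(self._ellipse_mask(180, 120))
        assert small.aspect_ratio == pytest.approx(large.aspect_ratio, rel=0.01)

    def test_multi_object_rejected(self):
        mask = np.zeros((100, 200), dtype=bool)
        mask[40:60, 20:60] = True
        mask[40:60, 120:160] = True
        with pytest.raises(morph.AmbiguityError):
            morph.measure_seed(mask)


class TestSegmentation:
    def test_three_disjoint_ellipses(self):
        spec = syn.SilhouetteSpec(
            half_length=60.0,
            half_width=35.0,
            image_size=(256, 512),
            centers=[(90.0, 90.0), (260.0, 90.0), (420.0, 170.0)],
        )
        image, truth = syn.make_silhouette_image(spec, rng_seed=5)
        labels = morph.segment_seeds(image)
        assert labels.max() == 3
        areas = sorted(int((labels == lab).sum()) for lab in (1, 2, 3))
        for area in areas:
            assert area == pytest.approx(np.pi * 60 * 35, rel=0.02)

    def test_tangent_pair_separated(self):
        spec = syn.SilhouetteSpec(
            half_length=60.0,
            half_width=35.0,
            image_size=(256, 400),
            centers=[(130.0, 128.0), (250.0, 128.0)],
        )
        image, _ = syn.make_silhouette_image(spec, rng_seed=5)
        labels = morph.segment_seeds(image)
        assert labels.max() == 2

    def test_background_only_image_yields_no_objects(self):
        rng = np.random.default_rng(0)
        image = 0.25 + rng.normal(0.0, 0.02, (128, 128))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = morph.segment_seeds(image)
        assert labels.max() == 0

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            morph.segment_seeds(np.ones((64, 64)))

    def test_area_conservation(self):
        spec = syn.SilhouetteSpec(
            half_length=50.0, half_width=30.0, image_size=(200, 200), centers=[(100.0, 100.0)]
        )
        image, _ = syn.make_silhouette_image(spec, rng_seed=1)
        labels = morph.segment_seeds(image)
        thr = morph.threshold_huang(image)
        from scipy import ndimage

        binary = ndimage.binary_fill_holes(image > thr)
        assert (labels > 0).sum() == pytest.approx(binary.sum(), rel=0.01)

    def test_huang_threshold_separates_bimodal(self):
        rng = np.random.default_rng(1)
        lo = rng.normal(0.2, 0.02, 5000)
        hi = rng.normal(0.8, 0.02, 3000)
        thr = morph.threshold_huang(np.concatenate([lo, hi]).reshape(80, 100))
        # the entropy valley spans the gap between the modes; any point in
        # it classifies the two populations almost perfectly
        assert (lo < thr).mean() > 0.999
        assert (hi > thr).all()


@pytest.fixture(scope="module")
def sheet_tess():
    sheet = syn.make_sheet_mesh(100.0, 100.0, 16)
    return syn.tessellate_surface(sheet, 25, rng_seed=3)


class TestCellGrowthMap:
    @pytest.mark.parametrize("seed", range(10))
    def test_stretch_recovery_across_seeds(self, seed):
        sheet = syn.make_sheet_mesh(100.0, 100.0, 16)
        t0 = syn.tessellate_surface(sheet, 25, rng_seed=seed)
        t1, lineage = syn.make_paired_tessellation(t0, 1.2, 1.0, 0.0, rng_seed=seed + 100)
        g = morph.cell_growth_map(t0, t1, lineage)
        assert g["areal_growth"].mean() == pytest.approx(0.20, abs=0.01)
        assert g["anisotropy"].mean() == pytest.approx(1.20, abs=0.02)
        axis_dev = np.minimum(g["main_axis_deg"], 180.0 - g["main_axis_deg"])
        assert axis_dev.max() < 5.0  # main axis along x

    def test_identity_map(self, sheet_tess):
        t1, lineage = syn.make_paired_tessellation(sheet_tess, 1.0, 1.0, 0.0, rng_seed=1)
        g = morph.cell_growth_map(sheet_tess, t1, lineage)
        assert np.allclose(g["areal_growth"], 0.0, atol=1e-9)
        assert np.allclose(g["anisotropy"], 1.0, atol=1e-9)

    def test_pure_rotation_is_isometry(self, sheet_tess):
        from seedmech.mesh import CellTessellation, SurfaceMesh

        ang = np.deg2rad(30.0)
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        mesh1 = SurfaceMesh(sheet_tess.mesh.vertices @ R.T, sheet_tess.mesh.faces)
        ids = {int(c): frozenset({int(c)}) for c in sheet_tess.cell_ids}
        t1 = CellTessellation(mesh1, sheet_tess.face_cell.copy())
        g = morph.cell_growth_map(sheet_tess, t1, ids)
        assert np.allclose(g["areal_growth"], 0.0, atol=0.01)
        assert np.allclose(g["anisotropy"], 1.0, atol=0.02)

    def test_divisions_counted(self, sheet_tess):
        t1, lineage = syn.make_paired_tessellation(sheet_tess, 1.1, 1.0, 1.0, rng_seed=2)
        g = morph.cell_growth_map(sheet_tess, t1, lineage)
        assert (g["n_offspring"] == 2).all()
        assert g["areal_growth"].mean() == pytest.approx(0.10, abs=0.01)

    def test_missing_parent_rejected(self, sheet_tess):
        t1, lineage = syn.make_paired_tessellation(sheet_tess, 1.1, 1.0, 0.0, rng_seed=2)
        lineage = dict(lineage)
        lineage.pop(int(sheet_tess.cell_ids[0]))
        with pytest.raises(morph.LineageError):
            morph.cell_growth_map(sheet_tess, t1, lineage)


class TestDimensionChange:
    def _table(self, n, seed_id=None, factor=(1.0, 1.0, 1.0)):
        df = pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "length": np.full(n, 10.0) * factor[0],
                "width": np.full(n, 5.0) * factor[1],
                "thickness": np.full(n, 2.0) * factor[2],
            }
        )
        if seed_id is not None:
            df["seed_id"] = seed_id
        return df

    def test_uniform_thickness_increase(self):
        before = self._table(50)
        after = self._table(50, factor=(1.0, 1.0, 1.10))
        _, per_seed = morph.dimension_change_stats(before, after)
        assert per_seed["median_pct_change_thickness"].iloc[0] == pytest.approx(10.0)
        assert per_seed["median_pct_change_length"].iloc[0] == pytest.approx(0.0)

    def test_median_robust_to_outlier(self):
        before = self._table(51)
        after = self._table(51, factor=(1.0, 1.0, 1.10))
        after.loc[0, "thickness"] = 100.0  # wild segmentation error
        _, per_seed = morph.dimension_change_stats(before, after)
        assert per_seed["median_pct_change_thickness"].iloc[0] == pytest.approx(10.0)

    def test_per_seed_grouping(self):
        before = pd.concat([self._table(10, "s1"), self._table(10, "s2")])
        after = pd.concat(
            [self._table(10, "s1", (1.05, 1.0, 1.0)), self._table(10, "s2", (1.20, 1.0, 1.0))]
        )
        _, per_seed = morph.dimension_change_stats(before, after)
        result = per_seed.set_index("seed_id")["median_pct_change_length"]
        assert result["s1"] == pytest.approx(5.0)
        assert result["s2"] == pytest.approx(20.0)

    def test_mismatched_ids_rejected(self):
        before = self._table(10)
        after = self._table(12)
        with pytest.raises(morph.JoinError):
            morph.dimension_change_stats(before, after)
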