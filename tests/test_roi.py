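import numpy as np
import pandas as pd
import pytest

import gazedecode as gd
from gazedecode.roi import (BalanceError, DegenerateROIError, PowerSpec,
                            rm_anova_power)

from conftest import make_dataset


@pytest.fixture(scope="module")
def geometry_366():
    # exactly 36.6 px per dva on both axes
    import math
    d = 58.0
    px_per_cm = 36.6 / (d * math.tan(math.radians(1.0)))
    return gd.ScreenGeometry(d, (1920, 1080),
                             (1920 / px_per_cm, 1080 / px_per_cm))


class TestRasterizeEllipse:
    def test_circle_area_matches_analytic(self):
        roi = gd.rasterize_ellipse("a", (200, 150), (40, 40), 0.0,
                                   (400, 300))
        assert roi.area_px == pytest.approx(np.pi * 40 ** 2, rel=0.02)

    def test_rotation_90_swaps_axes(self):
        a = gd.rasterize_ellipse("a", (200, 150), (80, 30), 0.0, (400, 300))
        b = gd.rasterize_ellipse("a", (200, 150), (80, 30), 90.0,
                                 (400, 300))
        assert a.extent_px("x") == pytest.approx(b.extent_px("y"), abs=1)
        assert a.extent_px("y") == pytest.approx(b.extent_px("x"), abs=1)

    def test_offscreen_centre_clipped(self):
        roi = gd.rasterize_ellipse("a", (-20, 150), (60, 40), 0.0,
                                   (400, 300))
        assert roi.raster[:, 0].any()
        assert roi.area_px < np.pi * 60 * 40

    def test_disjoint_ellipse_rejected(self):
        from gazedecode.geometry import GeometryError
        with pytest.raises(GeometryError):
            gd.rasterize_ellipse("a", (-500, -500), (30, 30), 0.0,
                                 (400, 300))


class TestMorphology:
    def test_erosion_extent_reduction_in_dva(self, geometry_366):
        # 0.78 dva disc on a (100, 60) px ellipse: the full major-axis
        # extent shrinks by ~2 x 0.78 = 1.6 dva
        roi = gd.rasterize_ellipse("a", (320, 240), (100, 60), 0.0,
                                   (640, 480))
        smaller = gd.erode_roi(roi, 0.78, geometry_366)
        reduction_dva = (roi.extent_px("x") - smaller.extent_px("x")) / 36.6
        assert reduction_dva == pytest.approx(1.6, abs=0.1)

    def test_opening_is_subset_of_original(self, geometry_366):
        roi = gd.rasterize_ellipse("a", (320, 240), (100, 60), 20.0,
                                   (640, 480))
        opened = gd.dilate_roi(gd.erode_roi(roi, 0.5, geometry_366), 0.5,
                               geometry_366)
        assert not (opened.raster & ~roi.raster).any()

    def test_disc_radius_1_on_3x3_square(self, unit_geometry):
        mask = np.zeros((9, 9), dtype=bool)
        mask[3:6, 3:6] = True
        roi = gd.EllipseROI("a", (4, 4), (1.5, 1.5), 0.0, mask)
        eroded = gd.erode_roi(roi, 1.0, unit_geometry)
        # brute-force oracle: only the centre survives a radius-1 disc
        expected = np.zeros((9, 9), dtype=bool)
        expected[4, 4] = True
        np.testing.assert_array_equal(eroded.raster, expected)

    def test_erosion_to_empty_is_degenerate(self, geometry_366):
        roi = gd.rasterize_ellipse("a", (320, 240), (10, 10), 0.0,
                                   (640, 480))
        with pytest.raises(DegenerateROIError):
            gd.erode_roi(roi, 0.78, geometry_366)


class TestProportionInROI:
    def _roi(self):
        return {"imgA": gd.rasterize_ellipse("imgA", (100, 100), (50, 50),
                                             0.0, (400, 300))}

    def test_all_inside_is_one(self):
        rows = [("p1", "imgA", "sound", 1, i, 100.0, 100.0 + i)
                for i in range(1, 5)]
        table = gd.proportion_in_roi(make_dataset(rows), self._roi())
        assert table["proportion"].tolist() == [1.0]

    def test_partial_counts(self):
        rows = [("p1", "imgA", "sound", 1, i, 100.0, 100.0)
                for i in range(1, 4)]
        rows += [("p1", "imgA", "sound", 1, i, 300.0, 250.0)
                 for i in range(4, 13)]
        table = gd.proportion_in_roi(make_dataset(rows), self._roi())
        assert table["proportion"].tolist() == [0.25]

    def test_shrinking_roi_never_increases_proportion(self, effect_dataset):
        big = {"img1": gd.rasterize_ellipse(
            "img1", (250, 168), (90, 70), 0.0, (320, 240))}
        small = {"img1": gd.erode_roi(big["img1"], 0.5,
                                      effect_dataset.geometry)}
        t_big = gd.proportion_in_roi(effect_dataset, big)
        t_small = gd.proportion_in_roi(effect_dataset, small)
        merged = t_big.merge(t_small,
                             on=["participant", "image", "condition"])
        assert (merged["proportion_y"] <= merged["proportion_x"] + 1e-12
                ).all()

    def test_missing_roi_is_error(self, effect_dataset):
        with pytest.raises(KeyError):
            gd.proportion_in_roi(effect_dataset, {})

    def test_out_of_image_fixations_excluded(self):
        rows = [("p1", "imgA", "sound", 1, 1, 100.0, 100.0),
                ("p1", "imgA", "sound", 1, 2, 900.0, 100.0)]
        table = gd.proportion_in_roi(make_dataset(rows), self._roi())
        assert table["proportion"].tolist() == [1.0]
        assert table["n_fixations"].tolist() == [1]


def random_table(rng, n_subj=6, n_img=10):
    rows = []
    for s in range(n_subj):
        for i in range(n_img):
            for c in ("no_sound", "sound"):
                rows.append({"participant": f"p{s}", "image": f"i{i:02d}",
                             "condition": c,
                             "proportion": rng.random()})
    return pd.DataFrame(rows)


class TestRMAnova:
    def test_constant_table_all_f_zero(self):
        t = random_table(np.random.default_rng(0))
        t["proportion"] = 0.4
        res = gd.rm_anova_2x10(t)
        for eff in res.effects.values():
            assert eff.f == 0.0
            assert eff.partial_eta_sq == 0.0

    def test_dfs_for_n6_2x10(self):
        res = gd.rm_anova_2x10(random_table(np.random.default_rng(1)))
        assert (res.effects["condition"].df,
                res.effects["condition"].error_df) == (1, 5)
        assert (res.effects["image"].df,
                res.effects["image"].error_df) == (9, 45)
        assert (res.effects["condition:image"].df,
                res.effects["condition:image"].error_df) == (9, 45)

    def test_ss_decomposition_complete(self):
        res = gd.rm_anova_2x10(random_table(np.random.default_rng(2)))
        parts = res.ss_subject + sum(
            e.ss + e.error_ss for e in res.effects.values())
        assert parts == pytest.approx(res.ss_total, rel=1e-8)

    def test_matches_design_matrix_oracle(self):
        # independent oracle: explicit projection onto effect subspaces
        rng = np.random.default_rng(3)
        t = random_table(rng, n_subj=5, n_img=4)
        res = gd.rm_anova_2x10(t)
        cube = (t.pivot_table(index="participant",
                              columns=["condition", "image"],
                              values="proportion")
                .to_numpy().reshape(5, 2, 4))

        def centering(k):
            return np.eye(k) - np.ones((k, k)) / k

        n, a, b = cube.shape
        x = cube.reshape(n, a * b)
        # effect projectors via Kronecker structure on the (a*b) axis
        Pa = np.kron(centering(a), np.ones((b, b)) / b)
        Pb = np.kron(np.ones((a, a)) / a, centering(b))
        Pab = np.kron(centering(a), centering(b))
        mean_subj = x.mean(axis=0, keepdims=True)
        for proj, name in [(Pa, "condition"), (Pb, "image"),
                           (Pab, "condition:image")]:
            ss_eff = (n * mean_subj @ proj @ mean_subj.T).item()
            resid = (x - mean_subj) @ proj
            ss_err = float(np.sum(resid * ((x - mean_subj) @ proj.T)))
            assert res.effects[name].ss == pytest.approx(ss_eff, rel=1e-8)
            assert res.effects[name].error_ss == pytest.approx(ss_err,
                                                               rel=1e-8)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        t = random_table(np.random.default_rng(4))
        res = gd.rm_anova_2x10(t)
        aov = pg.rm_anova(data=t, dv="proportion",
                          within=["condition", "image"],
                          subject="participant", detailed=True)
        by_source = aov.set_index("Source")
        assert res.effects["condition"].f == pytest.approx(
            by_source.loc["condition", "F"], rel=1e-6)
        assert res.effects["image"].f == pytest.approx(
            by_source.loc["image", "F"], rel=1e-6)
        assert res.effects["condition:image"].f == pytest.approx(
            by_source.loc["condition * image", "F"], rel=1e-6)

    def test_missing_cell_is_balance_error(self):
        t = random_table(np.random.default_rng(5)).iloc[:-1]
        with pytest.raises(BalanceError):
            gd.rm_anova_2x10(t)


class TestPower:
    def test_default_settings_require_six(self):
        assert gd.required_sample_size(PowerSpec()) == 6

    def test_classic_f_025_example(self):
        # benchmark case: f = 0.25 (eta2 ~ .0588), m = 4, corr .5 -> n ~ 24
        spec = PowerSpec(eta_sq=0.0625 / 1.0625,
                         effect_size_convention="gpower")
        assert gd.required_sample_size(spec) in (23, 24)

    def test_huge_effect_needs_few_subjects(self):
        assert gd.required_sample_size(PowerSpec(eta_sq=0.9)) <= 3

    def test_power_monotone_in_target(self):
        ns = [gd.required_sample_size(PowerSpec(target_power=p))
              for p in (0.5, 0.7, 0.8, 0.9, 0.95)]
        assert ns == sorted(ns)

    def test_matches_pingouin_under_gpower_convention(self):
        pg = pytest.importorskip("pingouin")
        spec = PowerSpec(eta_sq=0.14, effect_size_convention="gpower")
        ours = rm_anova_power(spec, 8)
        theirs = pg.power_rm_anova(eta_squared=0.14, m=4, n=8)
        assert ours == pytest.approx(theirs, rel=1e-9)
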