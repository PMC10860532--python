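import numpy as np
import pytest

from decontrast3d.volume import Volume
from decontrast3d.phantom import LabelMap
from decontrast3d.preprocess import NormalizationSpec
from decontrast3d.evaluation import (
    CalibrationCurve,
    BeamSpec,
    default_calibration_curve,
    cosine_similarity,
    mse,
    structure_stats,
    hu_to_density,
    density_diff_percent,
    line_profile,
    wepl,
    depth_at_wepl,
    range_shift,
    aggregate_report,
    full_report,
)

NORM = NormalizationSpec((-1024.0, 1976.0))


class TestCosine:
    def test_identical_volumes_give_one(self, rng):
        v = Volume(rng.uniform(-500, 500, (6, 6, 6)))
        assert cosine_similarity(v, v.copy(), NORM) == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        # after [0,1] windowing: one voxel at window-top vs a different voxel
        norm = NormalizationSpec((0.0, 100.0))
        a = np.zeros((2, 2, 1))
        b = np.zeros((2, 2, 1))
        a[0, 0, 0] = 100.0
        b[1, 0, 0] = 100.0
        assert cosine_similarity(Volume(a), Volume(b), norm) == pytest.approx(0.0)

    def test_positive_scaling_invariance(self, rng):
        norm = NormalizationSpec((0.0, 1000.0))
        g = rng.uniform(0, 500, (5, 5, 5))
        assert cosine_similarity(Volume(g), Volume(1.7 * g), norm) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_explicit_formula(self, rng):
        a = Volume(rng.uniform(-500, 500, (4, 4, 4)))
        b = Volume(rng.uniform(-500, 500, (4, 4, 4)))
        lo, hi = NORM.low, NORM.high
        x = ((np.clip(a.grid, lo, hi) - lo) / (hi - lo)).ravel()
        y = ((np.clip(b.grid, lo, hi) - lo) / (hi - lo)).ravel()
        expected = float(sum(xi * yi for xi, yi in zip(x, y))) / (
            np.sqrt(sum(xi * xi for xi in x)) * np.sqrt(sum(yi * yi for yi in y))
        )
        assert cosine_similarity(a, b, NORM) == pytest.approx(expected, abs=1e-12)

    def test_zero_norm_rejected(self):
        z = Volume(np.full((2, 2, 2), -1024.0))
        with pytest.raises(ValueError):
            cosine_similarity(z, z.copy(), NORM)


class TestMse:
    def test_identical_volumes_zero(self, rng):
        v = Volume(rng.uniform(-100, 100, (4, 4, 4)))
        assert mse(v, v.copy(), NORM) == 0.0

    def test_constant_offset_squares(self):
        # c in normalized units: 150 HU over a 3000 HU window = 0.05
        a = Volume(np.full((3, 3, 3), 100.0))
        b = Volume(np.full((3, 3, 3), 250.0))
        assert mse(a, b, NORM) == pytest.approx(0.05**2, abs=1e-12)

    def test_matches_explicit_loop(self, rng):
        a = Volume(rng.uniform(-500, 500, (3, 3, 3)))
        b = Volume(rng.uniform(-500, 500, (3, 3, 3)))
        lo, hi = NORM.low, NORM.high
        total = 0.0
        for i in np.ndindex(a.shape):
            ya = (np.clip(a.grid[i], lo, hi) - lo) / (hi - lo)
            yb = (np.clip(b.grid[i], lo, hi) - lo) / (hi - lo)
            total += (ya - yb) ** 2
        assert mse(a, b, NORM) == pytest.approx(total / a.grid.size, abs=1e-12)


class TestStructureStats:
    def test_constant_mask_stats(self):
        grid = np.zeros((4, 4, 4))
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        grid[1:3, 1:3, 1:3] = 46.8
        labels[1:3, 1:3, 1:3] = 1
        df = structure_stats(Volume(grid), LabelMap(labels, {1: "liver"}))
        row = df.set_index("structure").loc["liver"]
        assert row["mean_hu"] == pytest.approx(46.8)
        assert row["sd_hu"] == pytest.approx(0.0)

    def test_two_voxel_population_sd(self):
        grid = np.zeros((2, 1, 1))
        grid[0] = 0.0
        grid[1] = 10.0
        labels = np.ones((2, 1, 1), dtype=np.int16)
        df = structure_stats(Volume(grid), LabelMap(labels, {1: "pair"}))
        assert df.loc[0, "mean_hu"] == pytest.approx(5.0)
        assert df.loc[0, "sd_hu"] == pytest.approx(5.0)  # divide-by-n convention

    def test_matches_masked_loop_oracle(self, rng):
        grid = rng.uniform(-200, 200, (5, 5, 5))
        labels = rng.integers(0, 3, (5, 5, 5)).astype(np.int16)
        lm = LabelMap(labels, {1: "a", 2: "b"})
        df = structure_stats(Volume(grid), lm).set_index("structure")
        for lid, name in [(1, "a"), (2, "b")]:
            vals = [grid[i] for i in np.ndindex(grid.shape) if labels[i] == lid]
            assert df.loc[name, "mean_hu"] == pytest.approx(np.mean(vals))
            assert df.loc[name, "sd_hu"] == pytest.approx(np.std(vals))

    def test_empty_mask_flagged_not_fabricated(self):
        grid = np.zeros((3, 3, 3))
        labels = np.zeros((3, 3, 3), dtype=np.int16)
        df = structure_stats(Volume(grid), LabelMap(labels, {4: "ghost"}))
        row = df.set_index("structure").loc["ghost"]
        assert row["n_voxels"] == 0 and np.isnan(row["mean_hu"])


class TestCalibration:
    def test_water_anchor(self):
        assert hu_to_density(0.0) == pytest.approx(1.000)

    def test_midpoint_linear_interpolation(self):
        curve = CalibrationCurve(((-100.0, 0.930), (0.0, 1.000)))
        assert hu_to_density(-50.0, curve) == pytest.approx(0.965)

    def test_monotone_over_scanned_grid(self):
        rho = hu_to_density(np.linspace(-1100, 2000, 500))
        assert np.all(np.diff(rho) >= 0)

    def test_clamped_extrapolation(self):
        curve = default_calibration_curve()
        assert hu_to_density(-5000.0, curve) == pytest.approx(curve.rho[0])
        assert hu_to_density(5000.0, curve) == pytest.approx(curve.rho[-1])

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ValueError):
            CalibrationCurve(((0.0, 1.0), (100.0, 0.9)))
        with pytest.raises(ValueError):
            CalibrationCurve(((0.0, 1.0), (0.0, 1.1)))


class TestDensityDiff:
    def test_identical_volumes_zero_percent(self, rng):
        v = Volume(rng.uniform(-100, 100, (4, 4, 4)))
        labels = LabelMap(np.ones((4, 4, 4), dtype=np.int16), {1: "roi"})
        df = density_diff_percent(v, v.copy(), labels)
        assert df.loc[0, "mean_pct"] == pytest.approx(0.0)

    def test_uniform_five_percent(self):
        curve = CalibrationCurve(((0.0, 1.00), (100.0, 1.05)))
        ref = Volume(np.zeros((3, 3, 3)))
        test = Volume(np.full((3, 3, 3), 100.0))
        labels = LabelMap(np.ones((3, 3, 3), dtype=np.int16), {1: "roi"})
        df = density_diff_percent(test, ref, labels, curve)
        assert df.loc[0, "mean_pct"] == pytest.approx(5.0)

    def test_matches_voxel_loop_oracle(self, rng):
        a = Volume(rng.uniform(-200, 300, (4, 4, 4)))
        b = Volume(rng.uniform(-200, 300, (4, 4, 4)))
        mask = rng.integers(0, 2, (4, 4, 4)).astype(np.int16)
        labels = LabelMap(mask, {1: "roi"})
        df = density_diff_percent(a, b, labels)
        vals = []
        for i in np.ndindex(a.shape):
            if mask[i] == 1:
                rt = hu_to_density(a.grid[i])
                rr = hu_to_density(b.grid[i])
                vals.append(abs(rt - rr) / rr * 100.0)
        assert df.loc[0, "mean_pct"] == pytest.approx(np.mean(vals), abs=1e-10)


class TestProfilesAndWepl:
    def beam(self):
        return BeamSpec(entry=(0, 2, 2), direction="+x", isocenter=(2, 2, 2))

    def test_uniform_volume_constant_profile(self):
        v = Volume(np.full((10, 5, 5), 40.0), (2.0, 1, 1))
        depths, vals = line_profile(v, self.beam())
        assert len(vals) == 10
        np.testing.assert_allclose(vals, 40.0)
        np.testing.assert_allclose(depths, np.arange(10) * 2.0)

    def test_profile_matches_direct_indexing(self, rng):
        v = Volume(rng.uniform(-100, 100, (8, 4, 4)))
        _, vals = line_profile(v, self.beam())
        np.testing.assert_array_equal(vals, v.grid[:, 2, 2])

    def test_negative_direction_traversal(self, rng):
        v = Volume(rng.uniform(-100, 100, (8, 4, 4)))
        beam = BeamSpec(entry=(7, 2, 2), direction="-x", isocenter=(3, 2, 2))
        _, vals = line_profile(v, beam)
        np.testing.assert_array_equal(vals, v.grid[::-1, 2, 2])

    def test_water_path_wepl_equals_geometric_depth(self):
        # 100 voxels of water (0 HU) at 1 mm spacing -> 100 mm WEPL
        v = Volume(np.zeros((100, 3, 3)), (1.0, 1.0, 1.0))
        beam = BeamSpec(entry=(0, 1, 1), direction="+x", isocenter=(1, 1, 1))
        _, _, total = wepl(v, beam)
        assert total == pytest.approx(100.0)
        assert depth_at_wepl(v, beam, 50.0) == pytest.approx(50.0)

    def test_doubling_density_doubles_wepl(self):
        curve = CalibrationCurve(((0.0, 1.0), (1000.0, 2.0)))
        v1 = Volume(np.zeros((20, 3, 3)))
        v2 = Volume(np.full((20, 3, 3), 1000.0))
        beam = BeamSpec(entry=(0, 1, 1), direction="+x", isocenter=(1, 1, 1))
        assert wepl(v2, beam, curve)[2] == pytest.approx(2 * wepl(v1, beam, curve)[2])

    def test_beam_outside_volume_rejected(self):
        v = Volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="outside"):
            line_profile(v, BeamSpec((0, 9, 0), "+x", (1, 1, 1)))


class TestRangeShift:
    def water(self, n=100):
        return Volume(np.zeros((n, 3, 3)), (1.0, 1.0, 1.0))

    def beam(self):
        return BeamSpec(entry=(0, 1, 1), direction="+x", isocenter=(1, 1, 1))

    def test_identical_volumes_zero_shift(self):
        v = self.water()
        assert range_shift(v, v.copy(), self.beam()) == pytest.approx(0.0)

    def test_contrast_slab_pulls_range_proximal(self):
        # +122.9 HU (great-vessel enhancement) in a 20 mm slab crossing the
        # beam raises density there, so the enhanced volume reaches the
        # target WEPL at a shallower depth: negative shift, and its
        # magnitude matches the closed-form slab excess.
        curve = CalibrationCurve(((0.0, 1.0), (1000.0, 2.0)))  # rho = 1 + hu/1000
        a = self.water()
        b = self.water()
        b.grid[30:50] += 122.9
        shift = range_shift(a, b, self.beam(), curve, target_wepl=80.0)
        assert shift < 0
        # past the slab, depth_b satisfies: depth + 0.1229*20 extra WEPL
        expected = -0.1229 * 20.0
        assert shift == pytest.approx(expected, abs=1e-9)

    def test_antisymmetry(self, rng):
        a = Volume(rng.uniform(0, 80, (60, 3, 3)), (1.0, 1, 1))
        b = Volume(rng.uniform(0, 80, (60, 3, 3)), (1.0, 1, 1))
        beam = self.beam()
        s_ab = range_shift(a, b, beam, target_wepl=40.0)
        s_ba = range_shift(b, a, beam, target_wepl=40.0)
        assert s_ab == pytest.approx(-s_ba, abs=1e-10)

    def test_unreachable_target_names_volume(self):
        v = self.water(n=10)
        with pytest.raises(ValueError, match="'b'"):
            range_shift(self.water(100), v, self.beam(), target_wepl=50.0)


class TestAggregateReport:
    def test_printed_hu_difference_cells_average_to_4_72(self):
        rows = [{"hu_diff": v} for v in (4.8, 5.8, 5.3, 4.2, 3.5, 4.7)]
        assert aggregate_report(rows)["hu_diff"] == pytest.approx(4.72)

    def test_printed_density_difference_cells_average_to_0_40(self):
        rows = [{"pct": v} for v in (0.47, 0.45, 0.51, 0.42, 0.34, 0.20)]
        assert aggregate_report(rows)["pct"] == pytest.approx(0.40)

    def test_single_row_is_itself(self):
        assert aggregate_report([{"x": 3.14}])["x"] == pytest.approx(3.14)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report([])


class TestFullReport:
    def test_zero_enhancement_pair_reports_zero_differences(self):
        from decontrast3d.phantom import default_clinical_spec, generate_phantom
        from test_phantom import strip_enhancement

        spec = strip_enhancement(default_clinical_spec(seed=21))
        ncect, cect, labels = generate_phantom(spec)
        report = full_report(cect, ncect, cect, labels)
        for col in ("hu_diff_two_ncect", "hu_diff_cect",
                    "pct_diff_two_ncect", "pct_diff_cect"):
            assert report["summary"][col] == pytest.approx(0.0, abs=1e-9)
        assert report["cosine_similarity"] == pytest.approx(1.0)
        assert report["mse"] == pytest.approx(0.0, abs=1e-12)

    def test_difference_columns_track_enhancement(self, clinical_phantom):
        _, ncect, cect, labels = clinical_phantom
        report = full_report(cect, ncect, cect, labels)
        table = report["per_structure"].set_index("structure")
        # great vessels carry the largest enhancement delta
        assert table.loc["great_vessels", "hu_diff_cect"] > \
            table.loc["esophagus", "hu_diff_cect"]
        assert report["summary"]["hu_diff_cect"] > 30
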