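import numpy as np
import pandas as pd
import pytest

from hypoxiq import spheroid3d as s3
from hypoxiq.config import SimulationConfig
from hypoxiq.synthetic import generate_spheroid_stack


def _disk_slice(shape, center, radius, level=100.0, bg=0.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    img = np.full(shape, float(bg))
    img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = level
    return img


class TestThresholdHuang:
    def test_separates_bimodal(self):
        rng = np.random.default_rng(0)
        img = np.concatenate(
            [rng.normal(20, 3, 4000), rng.normal(120, 10, 2000)]
        )
        thr = s3.threshold_huang(img)
        assert 25 < thr < 110
        lo, hi = img[:4000], img[4000:]
        mis = (lo > thr).mean() + (hi <= thr).mean()
        assert mis < 0.05

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            s3.threshold_huang(np.full((10, 10), 5.0))

    def test_scale_shift_tracks(self):
        rng = np.random.default_rng(1)
        img = np.concatenate([rng.normal(10, 1, 2000), rng.normal(50, 2, 2000)])
        t1 = s3.threshold_huang(img)
        t2 = s3.threshold_huang(img * 2 + 5)
        assert t2 == pytest.approx(2 * t1 + 5, rel=0.05)


class TestPreprocessStack:
    def _stack(self, green, red):
        return s3.SpheroidStack(
            green=green, red=red,
            z_um=np.arange(1, green.shape[0] + 1, dtype=float) * 10,
            pixel_size_um=2.0,
        )

    def test_identical_channels_factor_one(self):
        img = np.stack([_disk_slice((64, 64), (32, 32), 10)] * 3)
        _, _, _, factor = s3.preprocess_stack(self._stack(img, img.copy()),
                                              rollball_um=30)
        assert factor == pytest.approx(1.0, abs=0.05)

    def test_doubled_green_factor_half(self):
        img = np.stack([_disk_slice((64, 64), (32, 32), 10)] * 3)
        _, g, r, factor = s3.preprocess_stack(
            self._stack(img * 2, img.copy()), rollball_um=30
        )
        assert factor == pytest.approx(0.5, abs=0.05)

    def test_combined_at_least_each_channel(self):
        rng = np.random.default_rng(2)
        green = rng.uniform(0, 50, (3, 48, 48))
        red = rng.uniform(0, 50, (3, 48, 48))
        combined, g, r, _ = s3.preprocess_stack(self._stack(green, red),
                                                rollball_um=20)
        assert (combined >= g - 1e-9).all() and (combined >= r - 1e-9).all()

    def test_blank_stack_factor_one_with_warning(self):
        blank = np.zeros((3, 32, 32))
        with pytest.warns(UserWarning, match="normalization"):
            *_, factor = s3.preprocess_stack(self._stack(blank, blank.copy()),
                                             rollball_um=20)
        assert factor == 1.0


class TestSliceOutline:
    def test_synthetic_disk_iou(self):
        img = _disk_slice((128, 128), (64, 64), 40, level=100, bg=2)
        rng = np.random.default_rng(3)
        img += rng.normal(0, 1, img.shape)
        mask = s3.slice_outline(img, pixel_size_um=2.0)
        rr, cc = np.mgrid[:128, :128]
        truth = (rr - 64) ** 2 + (cc - 64) ** 2 <= 40**2
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou > 0.95

    def test_blank_slice_flagged(self):
        assert s3.slice_outline(np.zeros((64, 64)), 2.0) is None

    def test_mask_area_monotone_in_radius(self):
        areas = []
        for radius in (10, 20, 30, 40):
            img = _disk_slice((128, 128), (64, 64), radius, level=100, bg=2)
            mask = s3.slice_outline(img, 2.0)
            areas.append(mask.sum())
        assert areas == sorted(areas)


class TestFitSphere:
    def test_exact_recovery_from_true_radii(self):
        z = np.arange(10, 300, 10.0)
        z_c, R = 150.0, 140.0
        usable = np.abs(z - z_c) < R
        radii = np.sqrt(R**2 - (z[usable] - z_c) ** 2)
        geom = s3.fit_sphere_radii(radii, z[usable])
        assert geom.radius_um == pytest.approx(R, abs=1e-6)
        assert geom.z_center_um == pytest.approx(z_c, abs=1e-6)
        assert geom.rss == pytest.approx(0.0, abs=1e-12)

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError, match="3 usable"):
            s3.fit_sphere_radii(np.array([50.0]), np.array([10.0]))

    def test_degenerate_z_rejected(self):
        with pytest.raises(ValueError, match="same z"):
            s3.fit_sphere_radii(
                np.array([50.0, 50, 50]), np.array([10.0, 10, 10])
            )

    def test_mask_based_fit_close_on_rasterized_disks(self):
        R, z_c, px = 100.0, 110.0, 2.0
        z = np.arange(20, 210, 10.0)
        masks = []
        for zi in z:
            dz = zi - z_c
            if abs(dz) >= R:
                masks.append(None)
                continue
            r_px = np.sqrt(R**2 - dz**2) / px
            masks.append(_disk_slice((128, 128), (64, 64), r_px) > 0)
        geom = s3.fit_sphere(masks, z, px)
        assert geom.radius_um == pytest.approx(R, abs=2.0)
        assert geom.z_center_um == pytest.approx(z_c, abs=2.0)


class TestDistance3d:
    GEOM = s3.SphereGeometry(radius_um=100.0, z_center_um=0.0)

    def test_equatorial_rim_is_zero(self):
        d3, clamped = s3.distance_3d(0.0, 0.0, self.GEOM)
        assert d3 == 0.0 and not clamped

    def test_equatorial_center_is_radius(self):
        d3, _ = s3.distance_3d(100.0, 0.0, self.GEOM)
        assert d3 == pytest.approx(100.0)

    def test_worked_example(self):
        # z=60 => r_z=80; d2=30 => rho=50; d3 = 100 - sqrt(50^2+60^2)
        d3, _ = s3.distance_3d(30.0, 60.0, self.GEOM)
        assert d3 == pytest.approx(100 - np.sqrt(6100), abs=1e-9)

    def test_equatorial_identity_d3_equals_d2(self):
        for d2 in (0.0, 10.0, 55.5, 100.0):
            d3, _ = s3.distance_3d(d2, 0.0, self.GEOM)
            assert d3 == pytest.approx(d2, abs=1e-12)

    def test_monotone_in_d2_within_slice(self):
        d3s = [s3.distance_3d(d2, 40.0, self.GEOM)[0] for d2 in
               np.linspace(0, np.sqrt(100**2 - 40**2), 30)]
        assert all(a <= b + 1e-12 for a, b in zip(d3s, d3s[1:]))

    def test_slice_outside_sphere_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            s3.distance_3d(0.0, 150.0, self.GEOM)

    def test_outside_sphere_clamped(self):
        geom = s3.SphereGeometry(radius_um=100.0, z_center_um=0.0)
        # negative rho beyond the sphere: d2 > 2*r_z is impossible for real
        # cells but numerically reachable -> clamp
        d3, clamped = s3.distance_3d(190.0, 60.0, geom)
        assert d3 == 0.0 and clamped

    def test_brute_force_surface_sampling_oracle(self):
        # the nearest surface point lies in the meridian plane through the
        # cell, so a dense sweep of 10^5 polar angles is an exhaustive search
        rng = np.random.default_rng(5)
        psi = np.linspace(0, 2 * np.pi, 100_000, endpoint=False)
        surface_x = 100.0 * np.sin(psi)
        surface_z = 100.0 * np.cos(psi)
        for _ in range(1000):
            z = rng.uniform(-95, 95)
            r_z = np.sqrt(100**2 - z**2)
            d2 = rng.uniform(0, r_z)
            d3, _ = s3.distance_3d(d2, z, self.GEOM)
            x = r_z - d2
            brute = np.sqrt(
                (surface_x - x) ** 2 + (surface_z - z) ** 2
            ).min()
            assert abs(d3 - brute) < 0.1


class TestClassifyGreen:
    def test_paper_example(self):
        assert s3.classify_green(0.3, 0.7) == "green"

    def test_zero_green_is_red(self):
        assert s3.classify_green(0.0, 1.0) == "red"

    def test_boundary_is_strictly_greater(self):
        assert s3.classify_green(0.225, 0.775) == "red"
        assert s3.classify_green(0.2250001, 0.7749999) == "green"

    def test_zero_total_flagged(self):
        assert s3.classify_green(0.0, 0.0) is None


class TestRadialHistogram:
    def _cells(self, d3s, classes):
        return pd.DataFrame({"d3_um": d3s, "cls": classes})

    def test_bin_arithmetic(self):
        hist = s3.radial_histogram(
            self._cells([5.0, 15.0], ["green", "red"])
        )
        assert list(hist.bin) == [0, 1]
        assert hist.green_fraction.tolist() == [1.0, 0.0]

    def test_all_green(self):
        hist = s3.radial_histogram(
            self._cells([3, 13, 23, 33], ["green"] * 4)
        )
        assert (hist.n_cells > 0).all()
        assert (hist.green_fraction == 1.0).all()

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        n = 200
        cells = self._cells(
            rng.uniform(0, 80, n), rng.choice(["green", "red"], n)
        )
        hist = s3.radial_histogram(cells)
        nonempty = hist[hist.n_cells > 0]
        assert np.allclose(
            nonempty.green_fraction + nonempty.red_fraction, 1.0
        )

    def test_empty_bin_flagged(self):
        hist = s3.radial_histogram(self._cells([5.0, 25.0], ["green", "red"]))
        empty = hist[hist.bin == 1]
        assert empty.n_cells.iloc[0] == 0
        assert np.isnan(empty.green_fraction.iloc[0])


@pytest.mark.slow
class TestEndToEnd:
    def test_generator_closed_loop(self, spheroid_dataset):
        stack, truth, cfg = spheroid_dataset
        cells, hist, geom = s3.analyze_stack(stack)
        assert geom.radius_um == pytest.approx(
            truth.attrs["radius_um"], abs=5.0
        )
        first_below = hist.loc[hist.green_fraction < 0.5, "bin"].min()
        assert 4 <= first_below <= 6
        nonempty = hist[hist.n_cells > 0]
        assert np.allclose(
            nonempty.green_fraction + nonempty.red_fraction, 1.0
        )

    def test_distance_recovery_mae(self, spheroid_dataset):
        from scipy.spatial import cKDTree

        stack, truth, cfg = spheroid_dataset
        cells, _, _ = s3.analyze_stack(stack)
        errors = []
        for k in sorted(cells["slice"].unique()):
            t = truth[truth.slice == k]
            c = cells[cells["slice"] == k]
            if not len(t) or not len(c):
                continue
            tree = cKDTree(t[["row", "col"]].to_numpy())
            dist, idx = tree.query(c[["row", "col"]].to_numpy())
            ok = dist < 3
            errors.extend(
                np.abs(
                    c["d3_um"].to_numpy()[ok] - t["d3_um"].to_numpy()[idx[ok]]
                )
            )
        # tolerance: max(z_step / 2, 2 px * pixel size)
        assert np.mean(errors) < max(10 / 2, 2 * 2.0)
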