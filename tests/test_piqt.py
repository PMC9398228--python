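"""Image-quality metrics against hand/brute-force oracles and the synthetic
generator's ground truth."""

import numpy as np
import pytest

from mrlqa.core import AcquisitionSpec, ImageVolume, RoiSpec
from mrlqa.phantoms import GroundTruth, PhantomSpec, generate_piqt_images
from mrlqa.piqt import (
    DetectionError,
    UndefinedMetricError,
    central_frequency_check,
    compute_linearity,
    compute_pixel_size,
    compute_slice_profile,
    compute_snr,
    compute_uniformity,
)


def _flat_image(value=100.0, n=64, spacing=1.0):
    return ImageVolume(np.full((n, n, 1), value), (spacing, spacing, 1.0))


class TestSnr:
    def test_direct_ratio_without_correction(self):
        rng = np.random.default_rng(0)
        img = _flat_image(0.0, 128)
        img.voxels[:64] = 100.0
        sig = RoiSpec("rectangle", (-32.0, 0.0), extents_mm=(40.0, 40.0))
        bg = RoiSpec("rectangle", (32.0, 0.0), extents_mm=(40.0, 40.0))
        m = bg.mask(img)
        noise = rng.normal(size=int(m.sum()))
        img.voxels[m] = (noise - noise.mean()) / noise.std() * 2.0  # SD exactly 2
        snr = compute_snr(img, sig, bg, rayleigh_correct=False)
        assert snr == pytest.approx(50.0, rel=1e-6)

    def test_noiseless_image_is_undefined(self):
        img = _flat_image(100.0)
        roi = RoiSpec("rectangle", (0.0, 0.0), extents_mm=(20.0, 20.0))
        with pytest.raises(UndefinedMetricError):
            compute_snr(img, roi, roi)

    def test_monte_carlo_recovers_generator_truth(self):
        """With Rayleigh correction on, the mean estimate over repeats
        recovers the generator's true SNR (signal / per-channel sigma)."""
        spec = PhantomSpec(kind="piqt_grid", object_signal=100.0)
        acq = AcquisitionSpec()
        sig = RoiSpec("rectangle", (37.5, 37.5), extents_mm=(15.0, 15.0))
        bg = RoiSpec("rectangle", (-110.0, -110.0), extents_mm=(18.0, 18.0))
        true_snr = 69.3
        est = []
        for s in range(50):
            truth = GroundTruth(noise_sd=100.0 / true_snr, seed=100 + s)
            vol = generate_piqt_images(spec, acq, truth)["magnitude"]
            est.append(compute_snr(vol, sig, bg, rayleigh_correct=True))
        assert np.mean(est) == pytest.approx(true_snr, rel=0.03)


class TestUniformity:
    def test_constant_region_is_zero(self):
        img = _flat_image(42.0)
        roi = RoiSpec("circle", (0.0, 0.0), diameter_mm=30.0)
        assert compute_uniformity(img, roi) == 0.0

    def test_direct_formula(self):
        img = _flat_image(1.0)
        img.voxels[10, 10, 0] = 2.0
        roi = RoiSpec("rectangle", (0.0, 0.0), extents_mm=(60.0, 60.0))
        assert compute_uniformity(img, roi) == pytest.approx(100.0 / 3.0)

    def test_imposed_linear_shading_closed_form(self):
        """Linear shading reaching max ~ 1.25 min across the ROI: uniformity
        equals the closed form of the imposed profile at the sampled voxel
        centers (~11.1%)."""
        spec = PhantomSpec(kind="piqt_grid", object_signal=100.0)
        acq = AcquisitionSpec()
        shade = lambda x, y=None: 1.0 + 0.25 * (x + 90.0) / 180.0  # noqa: E731
        truth = GroundTruth(shading=shade)
        vol = generate_piqt_images(spec, acq, truth)["magnitude"]
        roi = RoiSpec("rectangle", (0.0, 37.5), extents_mm=(180.0, 10.0))
        # closed form evaluated at the extreme sampled voxel centers
        x, _, _ = vol.coordinate_grids()
        xs = x[:, 0, 0]
        xs_in = xs[np.abs(xs) <= 90.0]
        smax, smin = shade(xs_in.max()), shade(xs_in.min())
        expected = (smax - smin) / (smax + smin) * 100.0
        assert expected == pytest.approx(0.25 / 2.25 * 100.0, abs=0.15)
        assert compute_uniformity(vol, roi) == pytest.approx(expected, abs=0.02)

    def test_zero_sum_is_undefined(self):
        img = _flat_image(0.0)
        roi = RoiSpec("circle", (0.0, 0.0), diameter_mm=30.0)
        with pytest.raises(UndefinedMetricError):
            compute_uniformity(img, roi)

    def test_invariant_to_global_scaling(self):
        rng = np.random.default_rng(3)
        img = _flat_image(50.0)
        img.voxels += rng.uniform(0, 5, img.voxels.shape)
        roi = RoiSpec("circle", (0.0, 0.0), diameter_mm=40.0)
        u1 = compute_uniformity(img, roi)
        img.voxels *= 7.3
        assert compute_uniformity(img, roi) == pytest.approx(u1, rel=1e-12)


class TestLinearity:
    @pytest.fixture()
    def grid_spec(self):
        return PhantomSpec(kind="piqt_grid", object_signal=100.0)

    def test_undistorted_grid_is_zero(self, grid_spec):
        vol = generate_piqt_images(grid_spec, AcquisitionSpec(), GroundTruth())["magnitude"]
        res = compute_linearity(vol, grid_spec)
        assert res["max_abs_percent"] < 0.05

    def test_isotropic_scaling_reads_half_percent(self, grid_spec):
        """A 1.005 isotropic rescale reads +0.5% in every direction — the
        PIQT tolerance value."""
        truth = GroundTruth(distortion_field_mm=lambda p: 0.005 * np.asarray(p))
        vol = generate_piqt_images(grid_spec, AcquisitionSpec(), truth)["magnitude"]
        res = compute_linearity(vol, grid_spec)
        for v in res["per_direction_percent"].values():
            assert v == pytest.approx(0.5, abs=0.05)

    def test_anisotropic_scaling_matches_projection(self, grid_spec):
        """1.003 x / 0.999 y scaling: each direction reads the analytic
        projection of the scaling onto that ray."""
        scale = np.array([0.003, -0.001, 0.0])
        truth = GroundTruth(distortion_field_mm=lambda p: np.asarray(p) * scale)
        vol = generate_piqt_images(grid_spec, AcquisitionSpec(), truth)["magnitude"]
        res = compute_linearity(vol, grid_spec)
        sx, sy = 1.003, 0.999
        expected = {
            "E": (sx - 1) * 100, "W": (sx - 1) * 100,
            "N": (sy - 1) * 100, "S": (sy - 1) * 100,
        }
        diag = (np.hypot(sx, sy) / np.sqrt(2.0) - 1) * 100
        for d in ("NE", "NW", "SE", "SW"):
            expected[d] = diag
        for d, v in res["per_direction_percent"].items():
            assert v == pytest.approx(expected[d], abs=0.05)

    def test_translation_insensitivity(self, grid_spec):
        truth = GroundTruth(distortion_field_mm=lambda p: np.broadcast_to(
            np.array([3.0, -2.0, 0.0]), np.asarray(p).shape))
        vol = generate_piqt_images(grid_spec, AcquisitionSpec(), truth)["magnitude"]
        res = compute_linearity(vol, grid_spec)
        assert res["max_abs_percent"] < 0.05

    def test_missing_hole_is_reported(self, grid_spec):
        vol = generate_piqt_images(grid_spec, AcquisitionSpec(), GroundTruth())["magnitude"]
        # paint over the hole at (0, 0): body signal fills it
        idx = vol.mm_to_index((0.0, 0.0, 0.0))
        i, j = int(round(idx[0])), int(round(idx[1]))
        vol.voxels[i - 4: i + 5, j - 4: j + 5, 0] = 100.0
        with pytest.raises(DetectionError):
            compute_linearity(vol, grid_spec)


class TestSliceProfile:
    def test_rectangular_slice_equivalent_width(self):
        """Ideal 5 mm rectangular slab: FWHM and integral both 5.00 mm."""
        spec = PhantomSpec(kind="piqt_wedge", object_signal=100.0)
        acq = AcquisitionSpec(voxel_size_mm=(1.0, 1.0, 5.0), matrix=(256, 256, 1))
        vol = generate_piqt_images(spec, acq, GroundTruth(slice_thickness_mm=5.0))["magnitude"]
        for r in compute_slice_profile(vol, spec):
            assert r.fwhm_mm == pytest.approx(5.0, abs=0.02)
            assert r.integral_mm == pytest.approx(5.0, abs=0.02)

    def test_gaussian_slice_closed_forms(self):
        """Gaussian slice of SD sigma: FWHM = 2.355 sigma and equivalent
        width = 2.507 sigma, within 1%."""
        sigma = 2.0
        spec = PhantomSpec(kind="piqt_wedge", object_signal=100.0)
        acq = AcquisitionSpec(voxel_size_mm=(1.0, 1.0, 5.0), matrix=(256, 256, 1))
        truth = GroundTruth(slice_profile=lambda z: np.exp(-0.5 * (np.asarray(z) / sigma) ** 2))
        vol = generate_piqt_images(spec, acq, truth)["magnitude"]
        for r in compute_slice_profile(vol, spec):
            assert r.fwhm_mm == pytest.approx(2.3548 * sigma, rel=0.01)
            assert r.integral_mm == pytest.approx(np.sqrt(2 * np.pi) * sigma, rel=0.01)

    def test_thin_slab_inside_tolerance_window(self):
        """A simulated 4.93 mm slab lands inside the 4.65-5.15 mm FWHM
        QA tolerance window."""
        spec = PhantomSpec(kind="piqt_wedge", object_signal=100.0)
        acq = AcquisitionSpec(voxel_size_mm=(1.0, 1.0, 5.0), matrix=(256, 256, 1))
        vol = generate_piqt_images(spec, acq, GroundTruth(slice_thickness_mm=4.93))["magnitude"]
        for r in compute_slice_profile(vol, spec):
            assert 4.65 <= r.fwhm_mm <= 5.15


class TestPixelSize:
    def test_ideal_edge_one_sample_lsf(self):
        spec = PhantomSpec(kind="piqt_edge", object_signal=100.0)
        acq = AcquisitionSpec(voxel_size_mm=(1.2, 1.2, 5.0), matrix=(200, 200, 1))
        vol = generate_piqt_images(spec, acq, GroundTruth())["magnitude"]
        h, v = compute_pixel_size(vol, spec)
        assert h == pytest.approx(1.2, abs=1e-6)
        assert v == pytest.approx(1.2, abs=1e-6)

    def test_boxcar_blur_grows_by_one_sample(self):
        """A 1-pixel boxcar widens the LSF FWHM by exactly one sample
        spacing (discrete convolution oracle)."""
        acq = AcquisitionSpec(voxel_size_mm=(1.2, 1.2, 5.0), matrix=(200, 200, 1))
        sharp = PhantomSpec(kind="piqt_edge", object_signal=100.0)
        blurred = PhantomSpec(kind="piqt_edge", object_signal=100.0,
                              geometry={"edge_blur_px": 1})
        v0 = generate_piqt_images(sharp, acq, GroundTruth())["magnitude"]
        v1 = generate_piqt_images(blurred, acq, GroundTruth())["magnitude"]
        h0, _ = compute_pixel_size(v0, sharp)
        h1, _ = compute_pixel_size(v1, blurred)
        assert h1 - h0 == pytest.approx(1.2, abs=1e-6)

    def test_mild_blur_within_tolerance(self):
        """1.2 mm acquisition with mild blur stays under the 1.3 mm
        horizontal-pixel tolerance."""
        acq = AcquisitionSpec(voxel_size_mm=(1.2, 1.2, 5.0), matrix=(200, 200, 1))
        spec = PhantomSpec(kind="piqt_edge", object_signal=100.0)
        vol = generate_piqt_images(spec, acq, GroundTruth())["magnitude"]
        h, _ = compute_pixel_size(vol, spec)
        assert h < 1.3


class TestCentralFrequency:
    @pytest.mark.parametrize(
        "rel_offset,expect_pct,expect_ppm",
        [
            (0.0, 0.0, 0.0),
            (-1.8e-4, -0.018, -180.0),
            (-5e-6, -5e-4, -5.0),
        ],
    )
    def test_deviation_definitions(self, rel_offset, expect_pct, expect_ppm):
        meta = AcquisitionSpec()
        nominal = meta.nominal_f0_MHz
        out = central_frequency_check(meta, nominal * (1.0 + rel_offset))
        assert out["deviation_percent"] == pytest.approx(expect_pct, abs=1e-9)
        assert out["deviation_ppm"] == pytest.approx(expect_ppm, abs=1e-6)


class TestDailyReproducibility:
    def test_metric_covs_within_daily_envelopes(self):
        """Across noise realizations at generator SNR 50, metric COVs stay
        within the worst observed daily variability: SNR 5%, uniformity 6%,
        FWHM 0.6%, integral 1%, pixel size 4%."""
        acq = AcquisitionSpec()
        acq_w = AcquisitionSpec(voxel_size_mm=(1.0, 1.0, 5.0), matrix=(256, 256, 1))
        gspec = PhantomSpec(kind="piqt_grid", object_signal=100.0)
        wspec = PhantomSpec(kind="piqt_wedge", object_signal=100.0)
        espec = PhantomSpec(kind="piqt_edge", object_signal=100.0)
        sig = RoiSpec("rectangle", (37.5, 37.5), extents_mm=(15.0, 15.0))
        bg = RoiSpec("rectangle", (-110.0, -110.0), extents_mm=(18.0, 18.0))
        body = RoiSpec("circle", (0.0, 37.5), diameter_mm=30.0)
        snrs, unifs, fwhms, integrals, pixels = [], [], [], [], []
        for s in range(100):
            truth = GroundTruth(noise_sd=2.0, seed=4000 + s)  # SNR 50
            g = generate_piqt_images(gspec, acq, truth)["magnitude"]
            snrs.append(compute_snr(g, sig, bg))
            unifs.append(compute_uniformity(g, body, smoothing_mm=1.2))
            w = generate_piqt_images(wspec, acq_w, truth)["magnitude"]
            prof = compute_slice_profile(w, wspec)[0]
            fwhms.append(prof.fwhm_mm)
            integrals.append(prof.integral_mm)
            e = generate_piqt_images(espec, acq, truth)["magnitude"]
            pixels.append(compute_pixel_size(e, espec)[0])

        def cov(v):
            return np.std(v) / np.mean(v) * 100.0

        assert cov(snrs) <= 5.0
        assert cov(unifs) <= 6.0
        assert cov(fwhms) <= 0.6
        assert cov(integrals) <= 1.0
        assert cov(pixels) <= 4.0
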