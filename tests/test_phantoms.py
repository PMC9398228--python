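"""Generator correctness: noiseless limits, noise statistics, forward models,
geometry, and determinism."""

import dataclasses
import math

import numpy as np
import pytest

from mrlqa.core import AcquisitionSpec, InvalidSpecError, RoiSpec
from mrlqa.phantoms import (
    AmbiguousMatchingError,
    GroundTruth,
    InsufficientSeriesError,
    PhantomSpec,
    add_rician_noise,
    afi_signal_pair,
    fiducial_grid_positions,
    generate_field_series,
    generate_fiducial_volume,
    generate_piqt_images,
    generate_qmri_series,
    piqt_hole_positions,
)


class TestPiqtImages:
    def test_noiseless_limit_background_and_object(self):
        """Without noise, background is exactly 0 and the body interior
        exactly the object signal."""
        spec = PhantomSpec(kind="piqt_grid", object_signal=100.0)
        vol = generate_piqt_images(spec, AcquisitionSpec(), GroundTruth())["magnitude"]
        sl = vol.voxels[:, :, 0]
        assert sl[:10, :10].max() == 0.0  # far corner: background
        x, y, _ = vol.coordinate_grids()
        interior = (np.abs(x[:, :, 0] - 12.5) < 5) & (np.abs(y[:, :, 0] - 12.5) < 5)
        assert np.allclose(sl[interior], 100.0)

    def test_wedge_plateau_width_matches_ray_trace(self):
        """A 5 mm rectangular slice through a slope-0.2 wedge projects to a
        25 mm plateau: geometric ray-trace across the wedge."""
        spec = PhantomSpec(kind="piqt_wedge", object_signal=100.0)
        acq = AcquisitionSpec(voxel_size_mm=(1.0, 1.0, 5.0), matrix=(256, 256, 1))
        truth = GroundTruth(slice_thickness_mm=5.0)
        vol = generate_piqt_images(spec, acq, truth)["magnitude"]
        x, y, _ = vol.coordinate_grids()
        band = np.abs(y[0, :, 0] - 25.0) < 10.0  # upper wedge band center
        prof = vol.voxels[:, band, 0].mean(axis=1)
        # ray-trace oracle: plateau edges at +-(thickness/slope)/2 = +-12.5 mm
        xs = x[:, 0, 0]
        assert np.allclose(prof[np.abs(xs) < 11.5], 100.0)
        assert np.allclose(prof[np.abs(xs) > 13.5], 0.0)
        width_px = np.sum(prof >= 50.0)
        assert width_px == pytest.approx(25, abs=1)

    def test_grid_spacing_is_25mm(self):
        """Undistorted grid: nearest-neighbour hole spacing is the machined
        25 mm."""
        from mrlqa.piqt import _detect_hole_centroids

        spec = PhantomSpec(kind="piqt_grid")
        vol = generate_piqt_images(spec, AcquisitionSpec(), GroundTruth())["magnitude"]
        known = piqt_hole_positions(spec)
        measured, missing = _detect_hole_centroids(vol, known, 5.0)
        assert len(missing) == 0
        from scipy.spatial import cKDTree

        d, _ = cKDTree(measured).query(measured, k=2)
        assert d[:, 1] == pytest.approx(25.0, abs=0.1)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(InvalidSpecError):
            AcquisitionSpec(matrix=(0, 128, 1))
        with pytest.raises(InvalidSpecError):
            AcquisitionSpec(voxel_size_mm=(1.2, -1.2, 5.0))


class TestNoiseModel:
    def test_rayleigh_background_ratio(self):
        """Magnitude of pure complex noise is Rayleigh: mean/SD ~ 1.913."""
        rng = np.random.default_rng(7)
        m = add_rician_noise(np.zeros(40000), 3.0, rng)
        assert m.mean() / m.std() == pytest.approx(1.9131, rel=0.02)

    def test_determinism_and_seed_sensitivity(self):
        spec = PhantomSpec(kind="piqt_grid")
        acq = AcquisitionSpec()
        a = generate_piqt_images(spec, acq, GroundTruth(noise_sd=2.0, seed=5))["magnitude"]
        b = generate_piqt_images(spec, acq, GroundTruth(noise_sd=2.0, seed=5))["magnitude"]
        c = generate_piqt_images(spec, acq, GroundTruth(noise_sd=2.0, seed=6))["magnitude"]
        assert np.array_equal(a.voxels, b.voxels)
        assert not np.array_equal(a.voxels, c.voxels)


class TestFiducialPhantom:
    def test_known_grid_has_1932_markers_on_7_plates(self):
        pts = fiducial_grid_positions()
        assert len(pts) == 1932
        zs = np.unique(pts[:, 2])
        assert len(zs) == 7
        assert np.allclose(np.diff(zs), 55.0)
        # in-plane spacing of the machined grid
        plate = pts[pts[:, 2] == zs[0]][:, :2]
        from scipy.spatial import cKDTree

        d, _ = cKDTree(plate).query(plate, k=2)
        assert np.allclose(d[:, 1], 25.0)

    def test_identity_render_centroids(self, fiducial_identity):
        """Zero distortion: rendered marker centroids sit within 0.05 voxel
        of the known positions."""
        from mrlqa.distortion import detect_markers

        ms = detect_markers(
            fiducial_identity["vol"], fiducial_identity["known"], align=False
        )
        assert len(ms.known_mm) == 1932
        tol = 0.05 * float(min(fiducial_identity["vol"].spacing_mm))
        assert ms.magnitudes_mm.max() <= tol

    def test_refuses_ambiguous_distortion(self):
        spec = PhantomSpec(kind="fiducial3d")
        truth = GroundTruth(distortion_field_mm=lambda p: np.full_like(p, 9.0))
        with pytest.raises(AmbiguousMatchingError):
            generate_fiducial_volume(spec, truth)


class TestFieldSeries:
    def test_phase_difference_closed_form(self, cylinder_setup):
        """Uniform 50 Hz offset at dTE = 1.5 ms: phase difference
        2*pi*50*0.0015 = 0.4712 rad everywhere in the phantom."""
        truth = GroundTruth(b0_field_hz=50.0)
        out = generate_field_series(
            cylinder_setup["spec"], cylinder_setup["acq"], truth, "b0_dual_echo"
        )
        body = out["magnitude_te1"].voxels[:, :, 0] > 50.0
        dphi = out["phase_te2"].voxels[:, :, 0] - out["phase_te1"].voxels[:, :, 0]
        dphi = np.angle(np.exp(1j * dphi))
        assert np.allclose(dphi[body], 2 * np.pi * 50 * 1.5e-3)
        assert out["wrap_warning"] is False

    def test_wrap_flag_raised_beyond_range(self, cylinder_setup):
        truth = GroundTruth(b0_field_hz=400.0)
        out = generate_field_series(
            cylinder_setup["spec"], cylinder_setup["acq"], truth, "b0_dual_echo"
        )
        assert out["wrap_warning"] is True

    def test_b1_ratio_matches_steady_state_model(self, cylinder_setup):
        """b1_fraction 0.9 at nominal 60 deg: the dual-TR magnitude ratio
        equals the steady-state model evaluated at 54 deg."""
        truth = GroundTruth(b1_fraction=0.9)
        out = generate_field_series(
            cylinder_setup["spec"], cylinder_setup["acq"], truth, "b1_dual_tr"
        )
        body = out["tr1"].voxels[:, :, 0] > 10.0
        ratio = out["tr2"].voxels[:, :, 0][body] / out["tr1"].voxels[:, :, 0][body]
        s1, s2 = afi_signal_pair(math.radians(54.0), 30.0, 150.0)
        assert np.allclose(ratio, s2 / s1)

    def test_b1_identity(self, cylinder_setup):
        from mrlqa.fieldmaps import reconstruct_b1

        truth = GroundTruth(b1_fraction=1.0)
        out = generate_field_series(
            cylinder_setup["spec"], cylinder_setup["acq"], truth, "b1_dual_tr"
        )
        fm = reconstruct_b1(out["tr1"], out["tr2"], 30.0, 150.0, 60.0)
        vals = fm.values[fm.roi_mask()]
        assert np.allclose(vals, 100.0, atol=1e-9)


class TestQmriSeries:
    def test_vfa_signal_literal_evaluation(self, relaxometry_setup):
        """Spoiled steady-state forward signal for T1=1000, TR=20, a=22,
        S0=1000 equals the literal equation value 81.3563."""
        spec = dataclasses.replace(relaxometry_setup["spec"])
        truth = GroundTruth(t1_ms=[1000.0] * 14, t2_ms=[100.0] * 14)
        acq = relaxometry_setup["acq_vfa"]
        vols = generate_qmri_series(spec, acq, truth, "vfa")
        v22 = vols[1].voxels[:, :, 0]
        # independent literal evaluation of the forward equation
        e1 = math.exp(-20.0 / 1000.0)
        expected = 1000.0 * math.sin(math.radians(22)) * (1 - e1) / (
            1 - math.cos(math.radians(22)) * e1
        )
        assert expected == pytest.approx(81.3563, abs=2e-4)
        # vial interiors only (exclude anti-aliased rim voxels)
        x, y, _ = vols[1].coordinate_grids()
        x2, y2 = x[:, :, 0], y[:, :, 0]
        interior = np.zeros_like(v22, dtype=bool)
        for cx, cy in np.asarray(spec.geometry["vial_centers_mm"]):
            interior |= np.hypot(x2 - cx, y2 - cy) <= 6.0
        assert np.max(np.abs(v22[interior] - expected)) < 1e-9

    @pytest.mark.parametrize(
        "mode,tval,expected",
        [
            ("mese", {"t2": 100.0}, 500.0 * math.exp(-1.0)),  # TE=100 below
            ("dwi", {"adc": 1.1e-3}, 1000.0 * math.exp(-0.99)),  # b=900
        ],
    )
    def test_decay_closed_forms(self, mode, tval, expected):
        centers = [(0.0, 0.0)]
        spec = PhantomSpec(
            kind="vial_array",
            object_signal=500.0 if mode == "mese" else 1000.0,
            geometry={"vial_centers_mm": centers, "vial_diameter_mm": 20.0},
        )
        if mode == "mese":
            truth = GroundTruth(t1_ms=[1000.0], t2_ms=[tval["t2"]])
            acq = AcquisitionSpec(tr_ms=4000.0, te_ms_list=[50.0, 100.0],
                                  voxel_size_mm=(2.0, 2.0, 3.0), matrix=(64, 64, 1))
            vols = generate_qmri_series(spec, acq, truth, "mese")
            img = vols[-1].voxels[:, :, 0]  # TE = 100 ms (after dummy)
        else:
            truth = GroundTruth(adc_mm2_per_s=[tval["adc"]])
            acq = AcquisitionSpec(tr_ms=15000.0, te_ms_list=[149.0],
                                  b_values_s_per_mm2=[0.0, 900.0],
                                  voxel_size_mm=(2.0, 2.0, 3.0), matrix=(64, 64, 1))
            vols = generate_qmri_series(spec, acq, truth, "dwi")
            img = vols[-1].voxels[:, :, 0]
        center_val = img[32, 32]
        assert center_val == pytest.approx(expected, rel=1e-12)

    def test_mese_prepends_flagged_dummy_echo(self, relaxometry_setup):
        vols = generate_qmri_series(
            relaxometry_setup["spec"], relaxometry_setup["acq_mese"],
            relaxometry_setup["truth"], "mese",
        )
        assert len(vols) == 9
        assert vols[0].flags["dummy"] is True
        assert vols[0].flags["te_ms"] == pytest.approx(11.0)
        assert all(not v.flags["dummy"] for v in vols[1:])

    @pytest.mark.parametrize(
        "mode,acq_kwargs",
        [
            ("vfa", {"flip_angles_deg": [10.0]}),
            ("mese", {"te_ms_list": [30.0]}),
            ("dwi", {"b_values_s_per_mm2": [500.0]}),
        ],
    )
    def test_single_point_series_rejected(self, mode, acq_kwargs):
        spec = PhantomSpec(kind="vial_array",
                           geometry={"vial_centers_mm": [(0.0, 0.0)], "vial_diameter_mm": 20.0})
        truth = GroundTruth(t1_ms=[1000.0], t2_ms=[100.0], adc_mm2_per_s=[1e-3])
        acq = AcquisitionSpec(tr_ms=15000.0, matrix=(32, 32, 1),
                              voxel_size_mm=(2.0, 2.0, 3.0), **acq_kwargs)
        with pytest.raises(InsufficientSeriesError):
            generate_qmri_series(spec, acq, truth, mode)
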