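"""Daily image-quality metrics: SNR, uniformity, linearity, slice profile,
pixel size, and central-frequency deviation.

The SNR noise estimate defaults to the single-image background convention:
the SD of the magnitude background is divided by 0.655 to undo the Rayleigh
compression of pure-noise magnitude statistics (configurable).  Uniformity
follows (max-min)/(max+min) x 100% over an optionally low-pass-filtered
region.  Linearity compares measured against known phantom dimensions along
the eight compass directions through the grid center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import AcquisitionSpec, ImageVolume, RoiSpec
from .phantoms import PhantomSpec, piqt_hole_positions

__all__ = [
    "RAYLEIGH_SD_FACTOR",
    "SliceProfileResult",
    "UndefinedMetricError",
    "DetectionError",
    "compute_snr",
    "compute_uniformity",
    "compute_linearity",
    "compute_slice_profile",
    "compute_pixel_size",
    "central_frequency_check",
]

#: SD of the magnitude of pure complex Gaussian noise relative to the
#: per-channel sigma: sqrt(2 - pi/2) ~ 0.655 (Rayleigh background).
RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))


class UndefinedMetricError(ValueError):
    """The metric is undefined on this input (e.g. zero noise or max+min=0)."""


class DetectionError(ValueError):
    """A required structure (holes, edge, wedge) could not be detected."""


def compute_snr(
    img: ImageVolume,
    signal_roi: RoiSpec,
    noise_roi: RoiSpec,
    rayleigh_correct: bool = True,
) -> float:
    """Mean signal in a central phantom region over the background noise.

    With ``rayleigh_correct`` (default) the background SD is divided by
    0.655 to recover the per-channel noise sigma from Rayleigh-distributed
    magnitude background.
    """
    signal = float(np.mean(signal_roi.values(img)))
    sd = float(np.std(noise_roi.values(img)))
    if sd == 0.0:
        raise UndefinedMetricError("background SD is zero; SNR undefined")
    noise = sd / RAYLEIGH_SD_FACTOR if rayleigh_correct else sd
    return signal / noise


def compute_uniformity(img: ImageVolume, roi: RoiSpec, smoothing_mm: float = 0.0) -> float:
    """(max - min)/(max + min) x 100% over the (optionally smoothed) region.

    ``smoothing_mm`` is the FWHM of an in-plane Gaussian low-pass applied
    before taking the extrema (suppresses single-voxel noise).
    """
    vox = img.voxels
    if smoothing_mm > 0:
        sigma_vox = smoothing_mm / 2.3548 / img.spacing_mm[:2]
        vox = np.stack(
            [ndimage.gaussian_filter(vox[:, :, k], sigma_vox) for k in range(vox.shape[2])],
            axis=2,
        )
    vals = vox[roi.mask(img)]
    vmax, vmin = float(vals.max()), float(vals.min())
    if vmax + vmin == 0:
        raise UndefinedMetricError("max + min is zero; uniformity undefined")
    return (vmax - vmin) / (vmax + vmin) * 100.0


# -- linearity ---------------------------------------------------------------

_COMPASS = {
    "E": (1, 0), "NE": (1, 1), "N": (0, 1), "NW": (-1, 1),
    "W": (-1, 0), "SW": (-1, -1), "S": (0, -1), "SE": (1, -1),
}


def _detect_hole_centroids(img: ImageVolume, expected_mm: np.ndarray, hole_diameter_mm: float):
    """Intensity-weighted centroids of the dark holes, paired to the known
    grid (nearest expected position within half the grid spacing)."""
    sl = img.voxels[:, :, img.voxels.shape[2] // 2]
    body = ndimage.binary_fill_holes(sl > 0.5 * np.percentile(sl, 95))
    inv = np.where(body, np.percentile(sl, 95) - sl, 0.0)
    inv[inv < 0] = 0.0
    thr = 0.5 * inv.max()
    lab = measure.label(inv > thr)
    props = measure.regionprops(lab, intensity_image=inv)
    min_area = 0.15 * np.pi * (hole_diameter_mm / 2.0) ** 2 / (img.spacing_mm[0] * img.spacing_mm[1])
    cands = [p.centroid_weighted for p in props if p.area >= min_area]
    # refine on the unthresholded inverted image: the anti-aliased hole
    # indicator is symmetric about the true center, so a windowed weighted
    # centroid removes threshold-truncation bias
    win = int(np.ceil((hole_diameter_mm / 2.0 + 3.0) / min(img.spacing_mm[:2])))
    cands = [_windowed_centroid_2d(inv, c, win) for c in cands]
    cands_mm = np.array(
        [img.index_to_mm((c[0], c[1], 0))[:2] for c in cands]
    ) if cands else np.empty((0, 2))
    pair_r = 0.5 * _min_grid_spacing(expected_mm)
    measured = np.full_like(expected_mm, np.nan)
    for i, e in enumerate(expected_mm):
        if len(cands_mm) == 0:
            continue
        d = np.linalg.norm(cands_mm - e, axis=1)
        j = int(np.argmin(d))
        if d[j] <= pair_r:
            measured[i] = cands_mm[j]
    missing = np.where(np.isnan(measured[:, 0]))[0]
    return measured, missing


def _windowed_centroid_2d(weight: np.ndarray, start, radius: int, iters: int = 3):
    c = np.asarray(start, dtype=float)
    for _ in range(iters):
        lo = np.maximum(np.round(c).astype(int) - radius, 0)
        hi = np.minimum(np.round(c).astype(int) + radius + 1, weight.shape)
        patch = weight[lo[0]:hi[0], lo[1]:hi[1]]
        tot = patch.sum()
        if tot <= 0:
            return tuple(c)
        gi, gj = np.meshgrid(np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), indexing="ij")
        c = np.array([(gi * patch).sum() / tot, (gj * patch).sum() / tot])
    return tuple(c)


def _min_grid_spacing(pts: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pts).query(pts, k=2)
    return float(d[:, 1].min())


def compute_linearity(img: ImageVolume, grid: PhantomSpec) -> dict:
    """Percent deviation of measured vs known grid dimension along the eight
    compass directions through the grid center.

    Each direction's dimension is the distance from the central hole to the
    outermost hole on the exact ray; the deviation is
    (measured - actual)/actual x 100%.  Returns per-direction values plus
    mean, SD, and maximum absolute deviation.
    """
    known = piqt_hole_positions(grid)
    hole_d = grid.geom("hole_diameter_mm", 5.0)
    measured, missing = _detect_hole_centroids(img, known, hole_d)
    if len(missing):
        raise DetectionError(f"holes missing at grid nodes {missing.tolist()}")
    # the grid includes its center node; use it as the common origin
    ic = int(np.argmin(np.linalg.norm(known, axis=1)))
    per_dir = {}
    for name, (ux, uy) in _COMPASS.items():
        u = np.array([ux, uy], dtype=float)
        u /= np.linalg.norm(u)
        along = known @ u
        perp = np.abs(known @ np.array([-u[1], u[0]]))
        on_ray = (perp < 1e-6) & (along > 1e-6)
        if not on_ray.any():
            raise DetectionError(f"no grid nodes on ray {name}")
        io = int(np.where(on_ray)[0][np.argmax(along[on_ray])])
        d_actual = float(np.linalg.norm(known[io] - known[ic]))
        d_meas = float(np.linalg.norm(measured[io] - measured[ic]))
        per_dir[name] = (d_meas - d_actual) / d_actual * 100.0
    vals = np.array(list(per_dir.values()))
    return {
        "per_direction_percent": per_dir,
        "mean_percent": float(vals.mean()),
        "sd_percent": float(vals.std(ddof=1)),
        "max_abs_percent": float(np.abs(vals).max()),
    }


# -- slice profile -----------------------------------------------------------

@dataclass
class SliceProfileResult:
    fwhm_mm: float
    integral_mm: float
    profile: np.ndarray
    z_mm: np.ndarray


def _fwhm_linear(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum with linear interpolation between the
    bracketing samples (deterministic; no fitting)."""
    half = y.max() / 2.0
    above = y >= half
    if not above.any():
        raise UndefinedMetricError("profile never reaches half maximum")
    i0, i1 = np.argmax(above), len(above) - 1 - np.argmax(above[::-1])
    if i0 == 0:
        left = x[0] - (x[1] - x[0]) / 2.0
    else:
        f = (half - y[i0 - 1]) / (y[i0] - y[i0 - 1])
        left = x[i0 - 1] + f * (x[i0] - x[i0 - 1])
    if i1 == len(y) - 1:
        right = x[-1] + (x[-1] - x[-2]) / 2.0
    else:
        f = (half - y[i1 + 1]) / (y[i1] - y[i1 + 1])
        right = x[i1 + 1] - f * (x[i1 + 1] - x[i1])
    return float(abs(right - left))


def compute_slice_profile(img: ImageVolume, wedge: PhantomSpec) -> list:
    """Slice profile from the opposing wedge pair.

    The line profile across each wedge band is projected to through-plane mm
    by the wedge slope; FWHM uses linear interpolation at half maximum and
    the integral is the equivalent width sum(profile)/max * sample spacing.
    Returns one :class:`SliceProfileResult` per wedge.
    """
    slope = wedge.geom("wedge_slope", 0.2)
    band_half = wedge.geom("wedge_band_mm", 30.0) / 2.0
    gap = wedge.geom("wedge_gap_mm", 20.0)
    sl = img.voxels[:, :, img.voxels.shape[2] // 2]
    x, y, _ = img.coordinate_grids()
    xs, ys = x[:, 0, 0], y[0, :, 0]
    results = []
    for sign, ycent in ((+1.0, gap / 2.0 + band_half), (-1.0, -gap / 2.0 - band_half)):
        rows = np.abs(ys - ycent) <= band_half * 0.8
        prof = sl[:, rows].mean(axis=1)
        bg = np.median(prof)
        prof = prof - min(bg, prof.min())
        if prof.max() <= 0:
            raise DetectionError("wedge profile indistinguishable from background")
        z = sign * slope * xs
        order = np.argsort(z)
        z, prof = z[order], prof[order]
        dz = float(np.mean(np.diff(z)))
        fwhm = _fwhm_linear(z, prof)
        integral = float(prof.sum() / prof.max() * dz)
        results.append(SliceProfileResult(fwhm, integral, prof, z))
    return results


# -- pixel size --------------------------------------------------------------

def _lsf_fwhm_from_esf(esf: np.ndarray, spacing: float) -> float:
    lsf = np.abs(np.diff(esf))
    if lsf.max() <= 0:
        raise DetectionError("no edge found in profile")
    x = (np.arange(len(lsf)) + 0.5) * spacing
    return _fwhm_linear(x, lsf)


def compute_pixel_size(img: ImageVolume, edge: PhantomSpec) -> tuple:
    """Pixel size along (horizontal, vertical) from the line-spread function.

    The edge-spread function across each near-axis-perpendicular edge is
    differentiated to an LSF whose FWHM (mm) is reported: horizontal probes
    the frequency-encode axis, vertical the phase-encode axis.
    """
    sl = img.voxels[:, :, img.voxels.shape[2] // 2]
    out = []
    for axis in (0, 1):
        prof = sl.mean(axis=1 - axis)
        spacing = float(img.spacing_mm[axis])
        # analyse the rising edge on the low-index side
        imax = int(np.argmax(prof >= prof.max() * 0.9))
        lo = max(imax - 12, 0)
        esf = prof[lo: imax + 4]
        out.append(_lsf_fwhm_from_esf(esf, spacing))
    return tuple(out)


def central_frequency_check(meta: AcquisitionSpec, measured_f0_MHz: float) -> dict:
    """Deviation of the measured resonance frequency from gamma * B0."""
    nominal = meta.nominal_f0_MHz
    dev = (measured_f0_MHz - nominal) / nominal
    return {
        "nominal_MHz": nominal,
        "measured_MHz": measured_f0_MHz,
        "deviation_percent": dev * 100.0,
        "deviation_ppm": dev * 1e6,
    }
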