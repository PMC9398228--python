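"""3D geometric distortion from a fiducial-grid phantom volume.

Distortion at each marker is the vector from its known (machined) position
to its measured (image) position; the longitudinal QA quantity is the
maximum Euclidean distortion inside nested spheres centered at isocenter
(diameter of spherical volume, DSV, 20/30/40/50 cm with tolerances
1/2/4/20 mm).

Phantom setup error is removed by default with a rigid (translation +
rotation) least-squares pre-alignment of the measured to the known set,
separating couch/cradle placement from machine distortion; disable with
``align=False`` to analyse raw vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import filters, measure

from .core import ImageVolume

__all__ = [
    "MarkerSet",
    "DsvSummary",
    "MatchingFailureError",
    "EmptyRegionError",
    "DSV_TOLERANCES_MM",
    "detect_markers",
    "summarize_by_dsv",
    "render_heatmap",
    "rigid_align",
]

#: QA tolerance (mm) on the maximum distortion per DSV (cm).
DSV_TOLERANCES_MM = {20: 1.0, 30: 2.0, 40: 4.0, 50: 20.0}


class MatchingFailureError(ValueError):
    """Marker-to-grid pairing failed (duplicates or too many unpaired)."""


class EmptyRegionError(ValueError):
    """No markers inside the requested spherical volume."""


@dataclass
class MarkerSet:
    """Paired known/measured fiducial coordinates (mm, isocenter origin)."""

    known_mm: np.ndarray
    measured_mm: np.ndarray
    ids: np.ndarray = None
    missing_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.known_mm = np.asarray(self.known_mm, dtype=float)
        self.measured_mm = np.asarray(self.measured_mm, dtype=float)
        if self.known_mm.shape != self.measured_mm.shape:
            raise MatchingFailureError("known and measured sets must pair 1:1")
        if self.ids is None:
            self.ids = np.arange(len(self.known_mm))
        if not np.all(np.isfinite(self.measured_mm)):
            raise MatchingFailureError("non-finite measured coordinates")

    @property
    def vectors_mm(self) -> np.ndarray:
        return self.measured_mm - self.known_mm

    @property
    def magnitudes_mm(self) -> np.ndarray:
        return np.linalg.norm(self.vectors_mm, axis=1)


@dataclass
class DsvSummary:
    """Maximum distortion per DSV with tolerance comparison."""

    max_distortion_mm: dict
    tolerance_mm: dict
    passes: dict
    n_markers: dict


def rigid_align(measured: np.ndarray, known: np.ndarray):
    """Least-squares rigid (rotation + translation) transform of ``measured``
    onto ``known`` (Kabsch).  Returns the transformed points, R, t."""
    mc, kc = measured.mean(axis=0), known.mean(axis=0)
    H = (measured - mc).T @ (known - kc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = kc - R @ mc
    return measured @ R.T + t, R, t


def detect_markers(
    vol: ImageVolume,
    expected_known_mm: np.ndarray,
    align: bool = True,
    threshold: float | None = None,
    max_unpaired_fraction: float = 0.01,
) -> MarkerSet:
    """Detect fiducial markers and pair them with the known grid.

    Thresholds (Otsu by default), labels connected components, computes
    intensity-weighted centroids refined on the raw image, and pairs each
    centroid to the nearest expected position within half the grid spacing.
    With ``align`` (default) a rigid setup-error transform is removed before
    the distortion vectors are formed.
    """
    expected = np.asarray(expected_known_mm, dtype=float)
    data = vol.voxels
    thr = filters.threshold_otsu(data) if threshold is None else threshold
    lab = measure.label(data > thr)
    props = measure.regionprops(lab, intensity_image=data)
    cents = np.array([p.centroid_weighted for p in props]) if props else np.empty((0, 3))
    cents = _refine_centroids(vol, cents, thr)
    cents_mm = vol.origin_mm + cents * vol.spacing_mm if len(cents) else np.empty((0, 3))

    d, _ = cKDTree(expected).query(expected, k=2)
    pair_r = 0.5 * float(d[:, 1].min())
    measured = np.full(expected.shape, np.nan)
    used = {}
    if len(cents_mm):
        tree = cKDTree(cents_mm)
        dist, j = tree.query(expected, k=1)
        for i, (dd, jj) in enumerate(zip(dist, j)):
            if dd <= pair_r:
                if jj in used:
                    raise MatchingFailureError(
                        f"centroid {jj} claimed by markers {used[jj]} and {i}"
                    )
                used[jj] = i
                measured[i] = cents_mm[jj]
    paired = ~np.isnan(measured[:, 0])
    missing = np.where(~paired)[0]
    if len(missing) > max_unpaired_fraction * len(expected):
        raise MatchingFailureError(
            f"{len(missing)} of {len(expected)} markers unpaired "
            f"(> {max_unpaired_fraction:.0%})"
        )
    meas, known = measured[paired], expected[paired]
    if align and len(meas) >= 3:
        meas, _, _ = rigid_align(meas, known)
    return MarkerSet(known, meas, ids=np.where(paired)[0], missing_ids=missing)


def _refine_centroids(vol: ImageVolume, cents: np.ndarray, thr: float, radius_vox: int = 5):
    """Re-estimate each centroid from unthresholded intensities in a window
    around the label centroid; removes threshold-truncation bias.  The local
    median (the noise floor — each marker occupies a small fraction of its
    window) is subtracted so background noise neither dilutes nor jitters
    the weighted centroid."""
    if not len(cents):
        return cents
    data = vol.voxels
    shape = np.array(data.shape)
    out = np.empty_like(cents)
    for k, c in enumerate(cents):
        lo = np.maximum(np.round(c).astype(int) - radius_vox, 0)
        hi = np.minimum(np.round(c).astype(int) + radius_vox + 1, shape)
        patch = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        med = np.median(patch)
        mad = 1.4826 * np.median(np.abs(patch - med))
        # soft threshold at the robust noise level: radially symmetric in the
        # blob, zero in pure background, and exactly a no-op without noise
        patch = np.clip(patch - med - 3.0 * mad, 0.0, None)
        w = patch.sum()
        if w <= 0:
            out[k] = c
            continue
        idx = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
        out[k] = [float((g * patch).sum() / w) for g in idx]
    return out


def summarize_by_dsv(
    markers: MarkerSet,
    dsv_cm=(20, 30, 40, 50),
    tolerances_mm: dict | None = None,
) -> DsvSummary:
    """Maximum |distortion| over markers inside each sphere |known| <= DSV/2."""
    tolerances_mm = dict(DSV_TOLERANCES_MM if tolerances_mm is None else tolerances_mm)
    r_known = np.linalg.norm(markers.known_mm, axis=1)
    mags = markers.magnitudes_mm
    maxima, passes, counts = {}, {}, {}
    for dsv in dsv_cm:
        inside = r_known <= dsv * 10.0 / 2.0
        if not inside.any():
            raise EmptyRegionError(f"no markers inside DSV {dsv} cm")
        m = float(mags[inside].max())
        maxima[dsv] = m
        counts[dsv] = int(inside.sum())
        tol = tolerances_mm.get(dsv)
        passes[dsv] = bool(m <= tol) if tol is not None else None
    return DsvSummary(maxima, tolerances_mm, passes, counts)


def render_heatmap(markers: MarkerSet, plane: str = "axial", plate_z_mm: float | None = None):
    """Grid the per-marker |distortion| of one plate for visual baseline
    comparison.  Returns (grid_2d, x_coords, y_coords); NaN where no marker."""
    if plane != "axial":
        raise ValueError("only axial per-plate heatmaps are rendered")
    zs = markers.known_mm[:, 2]
    z0 = plate_z_mm if plate_z_mm is not None else zs[np.argmin(np.abs(zs))]
    sel = np.isclose(zs, z0)
    pts = markers.known_mm[sel][:, :2]
    mags = markers.magnitudes_mm[sel]
    xs = np.unique(pts[:, 0])
    ys = np.unique(pts[:, 1])
    grid = np.full((len(xs), len(ys)), np.nan)
    ix = np.searchsorted(xs, pts[:, 0])
    iy = np.searchsorted(ys, pts[:, 1])
    grid[ix, iy] = mags
    return grid, xs, ys
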