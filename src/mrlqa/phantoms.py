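"""Synthetic QA-phantom image generation with known ground truth.

Every downstream stage (PIQT metrics, 3D distortion, B0/B1 field mapping,
quantitative T1/T2/ADC) consumes images produced here, so each generator
renders its phantom from an analytically known ground truth:

* a periodic image-quality phantom (uniform body, 45-hole linearity grid,
  opposing wedge pair for the slice profile, step edges for resolution);
* a 7-plate fiducial grid (1932 markers, 25 mm in-plane / 55 mm between
  plates) optionally warped by a smooth distortion field;
* a 40-cm uniform cylinder scanned as dual-echo (B0) or dual-TR (B1)
  series over gantry angles;
* vial arrays with user-set nominal T1/T2/ADC imaged as variable-flip-angle,
  multi-echo spin-echo, or diffusion-weighted series.

Noise model: independent zero-mean Gaussian noise of standard deviation
``noise_sd`` is added to the real and imaginary channels before taking the
magnitude, so magnitude noise is Rician and pure-background voxels are
Rayleigh distributed (mean/SD ratio ~1.913).  Sub-voxel structure (hole and
vial edges, fiducial markers, wedge ramps) is rendered with anti-aliased /
smooth-blob intensity so centroids and profiles are defined to sub-voxel
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import AcquisitionSpec, ImageVolume, InvalidSpecError

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "AmbiguousMatchingError",
    "InsufficientSeriesError",
    "generate_piqt_images",
    "generate_fiducial_volume",
    "fiducial_grid_positions",
    "generate_field_series",
    "generate_qmri_series",
    "noise_sd_for_image_snr",
    "add_rician_noise",
    "default_relaxometry_vials",
    "default_diffusion_vials",
    "afi_signal_pair",
    "spgr_signal",
]

PIQT_GRID_SPACING_MM = 25.0
PIQT_HOLE_DIAMETER_MM = 5.0
PIQT_GRID_EXTENT_MM = 150.0
FIDUCIAL_INPLANE_SPACING_MM = 25.0
FIDUCIAL_PLATE_SPACING_MM = 55.0
FIDUCIAL_PLATE_RADIUS_MM = 231.0
FIDUCIAL_N_PLATES = 7


class AmbiguousMatchingError(ValueError):
    """Requested distortion is too large for unambiguous marker pairing."""


class InsufficientSeriesError(ValueError):
    """A quantitative fit needs more distinct acquisitions than provided."""


@dataclass
class PhantomSpec:
    """Physical description of a phantom build.

    ``geometry`` carries kind-specific dimensions in mm; missing entries fall
    back to the defaults of the emulated hardware (25 mm grid spacing, 5 mm
    holes, 150 mm grid extent, 55 mm plate spacing, 400 mm cylinder, ...).
    """

    kind: str = "piqt_grid"
    geometry: dict = field(default_factory=dict)
    background_signal: float = 0.0
    object_signal: float = 100.0

    KINDS = ("piqt_grid", "piqt_wedge", "piqt_edge", "fiducial3d", "cylinder", "vial_array")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise InvalidSpecError(f"unknown phantom kind {self.kind!r}")
        for key, val in self.geometry.items():
            if isinstance(val, (int, float)) and val <= 0 and key != "distortion_zero":
                raise InvalidSpecError(f"geometry entry {key!r} must be positive")

    def geom(self, key: str, default: float):
        return self.geometry.get(key, default)


@dataclass
class GroundTruth:
    """The simulated truth every estimator is later judged against.

    Fields are callables over machine coordinates (mm) where spatial
    variation is wanted, or scalars/None for uniform/absent effects.
    """

    #: per-vial nominal values, aligned with the vial centers of the spec
    t1_ms: list = None
    t2_ms: list = None
    adc_mm2_per_s: list = None
    #: static B0 offset field, callable (x, y) -> Hz, or scalar Hz
    b0_field_hz: object = 0.0
    #: additive gantry perturbation, callable (x, y, angle_deg) -> Hz
    b0_gantry_hz: object = None
    #: B1 as fraction of nominal (1.0 = nominal); callable (x, y) or scalar
    b1_fraction: object = 1.0
    #: smooth displacement field, callable (N,3) mm -> (N,3) mm
    distortion_field_mm: object = None
    #: multiplicative intensity shading, callable (x, y) -> factor
    shading: object = None
    #: through-plane slice-sensitivity profile, callable z_mm -> [0, 1];
    #: default: ideal 5 mm rectangular slice
    slice_profile: object = None
    slice_thickness_mm: float = 5.0
    #: per-channel SD of the complex Gaussian noise
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if self.t1_ms is not None and self.t2_ms is not None:
            for t1, t2 in zip(self.t1_ms, self.t2_ms):
                if not (t1 > t2 > 0):
                    raise InvalidSpecError("each vial requires T1 > T2 > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def slice_sensitivity(self, z_mm: np.ndarray) -> np.ndarray:
        if self.slice_profile is not None:
            return np.asarray(self.slice_profile(z_mm), dtype=float)
        return (np.abs(np.asarray(z_mm)) <= self.slice_thickness_mm / 2.0).astype(float)

    def eval_b0(self, x, y, gantry_angle_deg: float = 0.0):
        f = self.b0_field_hz(x, y) if callable(self.b0_field_hz) else float(self.b0_field_hz)
        f = np.broadcast_to(np.asarray(f, dtype=float), np.broadcast(x, y).shape).copy()
        if self.b0_gantry_hz is not None:
            f = f + self.b0_gantry_hz(x, y, gantry_angle_deg)
        return f

    def eval_b1(self, x, y):
        b1 = self.b1_fraction(x, y) if callable(self.b1_fraction) else float(self.b1_fraction)
        b1 = np.broadcast_to(np.asarray(b1, dtype=float), np.broadcast(x, y).shape)
        if np.any(b1 <= 0):
            raise InvalidSpecError("b1_fraction must be positive everywhere")
        return b1


def add_rician_noise(signal: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + complex Gaussian noise); Rician/Rayleigh statistics."""
    if noise_sd == 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, noise_sd, np.shape(signal))
    im = rng.normal(0.0, noise_sd, np.shape(signal))
    return np.hypot(re, im)


def _blank(acq: AcquisitionSpec) -> ImageVolume:
    shape = tuple(int(m) for m in acq.matrix)
    return ImageVolume(np.zeros(shape), np.asarray(acq.voxel_size_mm, dtype=float), meta=acq)


def _circle_coverage(x, y, cx, cy, radius, h):
    """Approximate per-pixel area coverage of a disc, linear in the signed
    distance to the rim (exact to O(h) and symmetric, so centroids are
    preserved)."""
    d = np.hypot(x - cx, y - cy) - radius
    return np.clip(0.5 - d / h, 0.0, 1.0)


def _rect_coverage(x, y, cx, cy, ex, ey, hx, hy):
    """Separable anti-aliased coverage of an axis-aligned rectangle with
    half-extents (ex, ey)."""
    fx = np.clip((ex - np.abs(x - cx)) / hx + 0.5, 0.0, 1.0)
    fy = np.clip((ey - np.abs(y - cy)) / hy + 0.5, 0.0, 1.0)
    return fx * fy


# ---------------------------------------------------------------------------
# PIQT phantoms
# ---------------------------------------------------------------------------

def piqt_hole_positions(spec: PhantomSpec) -> np.ndarray:
    """Known (x, y) hole centers: 7x7 grid at 25 mm spacing, corners removed
    (45 holes over a 150 x 150 mm^2 section)."""
    s = spec.geom("grid_spacing_mm", PIQT_GRID_SPACING_MM)
    n = int(spec.geom("grid_nodes", 7))
    idx = np.arange(n) - (n - 1) / 2.0
    pts = [
        (i * s, j * s)
        for i in idx
        for j in idx
        if not (abs(i) == idx.max() and abs(j) == idx.max())
    ]
    return np.array(pts)


def generate_piqt_images(spec: PhantomSpec, acq: AcquisitionSpec, truth: GroundTruth) -> dict:
    """Render the PIQT phantom image for the given section.

    Returns a dict with a single ``"magnitude"`` ImageVolume (plus the known
    hole centers for the grid section under ``"hole_centers_mm"``).
    """
    if spec.kind not in ("piqt_grid", "piqt_wedge", "piqt_edge"):
        raise InvalidSpecError("spec.kind must be a piqt_* phantom")
    vol = _blank(acq)
    x, y, _ = vol.coordinate_grids()
    x2, y2 = x[:, :, 0], y[:, :, 0]
    hx, hy = vol.spacing_mm[0], vol.spacing_mm[1]
    body_half = spec.geom("body_extent_mm", 190.0) / 2.0
    body = _rect_coverage(x2, y2, 0.0, 0.0, body_half, body_half, hx, hy)
    img = spec.object_signal * body

    out = {}
    if spec.kind == "piqt_grid":
        centers = piqt_hole_positions(spec)
        if truth.distortion_field_mm is not None:
            pts3 = np.column_stack([centers, np.zeros(len(centers))])
            centers = centers + truth.distortion_field_mm(pts3)[:, :2]
        r = spec.geom("hole_diameter_mm", PIQT_HOLE_DIAMETER_MM) / 2.0
        for cx, cy in centers:
            cov = _circle_coverage(x2, y2, cx, cy, r, 0.5 * (hx + hy))
            img = img * (1.0 - cov)
        out["hole_centers_mm"] = piqt_hole_positions(spec)
    elif spec.kind == "piqt_wedge":
        # Two opposing wedges map the through-plane slice-sensitivity profile
        # onto the readout axis: lateral position x corresponds to depth
        # z = +/- slope * (x - x0).  Rendered in two horizontal bands with
        # 8x in-plane supersampling along x.
        slope = spec.geom("wedge_slope", 0.2)  # dz/dx
        band_half = spec.geom("wedge_band_mm", 30.0) / 2.0
        gap = spec.geom("wedge_gap_mm", 20.0)
        nss = 32  # in-plane supersampling along the ramp axis
        sub = np.linspace(-0.5 + 0.5 / nss, 0.5 - 0.5 / nss, nss) * hx
        xs = x2[:, :, None] + sub[None, None, :]
        for sign, ycent in ((+1.0, gap / 2.0 + band_half), (-1.0, -gap / 2.0 - band_half)):
            prof = truth.slice_sensitivity(sign * slope * xs).mean(axis=2)
            band = _rect_coverage(x2, y2, 0.0, ycent, body_half, band_half, hx, hy)
            img = img * (1.0 - band) + spec.object_signal * prof * band
    else:  # piqt_edge
        # Bright rectangle whose vertical/horizontal edges probe the line
        # spread function along x and y.  Edges land on voxel boundaries by
        # default so the unblurred LSF is one sample wide.
        ex = spec.geom("edge_halfwidth_x_mm", 60.0)
        ey = spec.geom("edge_halfwidth_y_mm", 60.0)
        cov = _rect_coverage(x2, y2, 0.0, 0.0, ex, ey, hx, hy)
        blur_px = spec.geometry.get("edge_blur_px", 0)
        if blur_px:
            k = np.ones(int(blur_px) + 1) / (int(blur_px) + 1)
            cov = np.apply_along_axis(lambda a: np.convolve(a, k, mode="same"), 0, cov)
            cov = np.apply_along_axis(lambda a: np.convolve(a, k, mode="same"), 1, cov)
        img = spec.object_signal * cov

    if truth.shading is not None:
        img = img * truth.shading(x2, y2)
    img = img + spec.background_signal
    vol.voxels[:, :, 0] = add_rician_noise(img, truth.noise_sd, truth.rng())
    out["magnitude"] = vol
    return out


# ---------------------------------------------------------------------------
# 3D fiducial phantom
# ---------------------------------------------------------------------------

def fiducial_grid_positions(spec: PhantomSpec | None = None) -> np.ndarray:
    """Known machine coordinates of all fiducial markers.

    In-plane: a 25 mm grid restricted to a circular plate of radius 231 mm,
    excluding the exact center point (276 markers per plate).  Seven plates
    spaced 55 mm along z give 1932 markers, the central plate at isocenter.
    """
    spec = spec or PhantomSpec(kind="fiducial3d")
    s = spec.geom("inplane_spacing_mm", FIDUCIAL_INPLANE_SPACING_MM)
    dz = spec.geom("plate_spacing_mm", FIDUCIAL_PLATE_SPACING_MM)
    radius = spec.geom("plate_radius_mm", FIDUCIAL_PLATE_RADIUS_MM)
    nplates = int(spec.geom("n_plates", FIDUCIAL_N_PLATES))
    nmax = int(math.floor(radius / s))
    ij = np.arange(-nmax, nmax + 1) * s
    X, Y = np.meshgrid(ij, ij, indexing="ij")
    keep = (np.hypot(X, Y) <= radius) & ~((X == 0) & (Y == 0))
    xy = np.column_stack([X[keep], Y[keep]])
    zs = (np.arange(nplates) - (nplates - 1) / 2.0) * dz
    pts = np.concatenate([np.column_stack([xy, np.full(len(xy), z)]) for z in zs])
    return pts


def generate_fiducial_volume(
    spec: PhantomSpec,
    truth: GroundTruth,
    voxel_size_mm=(2.0, 2.0, 2.75),
    matrix=(244, 244, 132),
    marker_sigma_vox: float = 1.1,
    drop_ids=(),
):
    """Render the fiducial-grid volume under the truth distortion field.

    Markers are rendered as Gaussian blobs (sigma ``marker_sigma_vox``
    voxels) centered at known + distortion positions; sampling a smooth blob
    keeps the intensity-weighted centroid sub-voxel accurate.  Returns
    ``(ImageVolume, known_positions_mm)`` where the known positions are the
    undistorted machine coordinates (markers in ``drop_ids`` are excluded
    from the rendering but kept in the known list).
    """
    if spec.kind != "fiducial3d":
        raise InvalidSpecError("spec.kind must be 'fiducial3d'")
    known = fiducial_grid_positions(spec)
    if truth.distortion_field_mm is not None:
        disp = np.asarray(truth.distortion_field_mm(known), dtype=float)
    else:
        disp = np.zeros_like(known)
    spacing_min = min(
        spec.geom("inplane_spacing_mm", FIDUCIAL_INPLANE_SPACING_MM),
        spec.geom("plate_spacing_mm", FIDUCIAL_PLATE_SPACING_MM),
    )
    maxdisp = float(np.linalg.norm(disp, axis=1).max()) if len(disp) else 0.0
    if maxdisp > spacing_min / 2.0:
        raise AmbiguousMatchingError(
            f"max distortion {maxdisp:.2f} mm exceeds half the marker spacing "
            f"({spacing_min / 2.0:.2f} mm); pairing would be ambiguous"
        )
    acq = AcquisitionSpec(voxel_size_mm=tuple(voxel_size_mm), matrix=tuple(matrix))
    vol = _blank(acq)
    data = vol.voxels
    sig = np.asarray(marker_sigma_vox, dtype=float) * vol.spacing_mm
    rad = np.ceil(4.0 * marker_sigma_vox).astype(int)
    shape = np.array(data.shape)
    rendered = known + disp
    for mid, c in enumerate(rendered):
        if mid in drop_ids:
            continue
        ci = vol.mm_to_index(c)
        lo = np.maximum(np.floor(ci).astype(int) - rad, 0)
        hi = np.minimum(np.floor(ci).astype(int) + rad + 2, shape)
        if np.any(lo >= hi):
            continue
        ax = [vol.origin_mm[k] + np.arange(lo[k], hi[k]) * vol.spacing_mm[k] for k in range(3)]
        g = (
            np.exp(-0.5 * ((ax[0] - c[0]) / sig[0]) ** 2)[:, None, None]
            * np.exp(-0.5 * ((ax[1] - c[1]) / sig[1]) ** 2)[None, :, None]
            * np.exp(-0.5 * ((ax[2] - c[2]) / sig[2]) ** 2)[None, None, :]
        )
        data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += spec.object_signal * g
    vol.voxels = add_rician_noise(data, truth.noise_sd, truth.rng())
    return vol, known


# ---------------------------------------------------------------------------
# Field-mapping series (B0 dual-echo / B1 dual-TR) on the uniform cylinder
# ---------------------------------------------------------------------------

def spgr_signal(alpha_rad, tr_ms, t1_ms, s0=1.0):
    """Spoiled steady-state gradient-echo magnitude."""
    e1 = np.exp(-tr_ms / t1_ms)
    return s0 * np.sin(alpha_rad) * (1.0 - e1) / (1.0 - np.cos(alpha_rad) * e1)


def afi_signal_pair(alpha_rad, tr1_ms, tr2_ms, t1_ms=None, s0=1.0):
    """Signal pair of the interleaved dual-TR (actual-flip-angle) sequence.

    With ``t1_ms=None`` the ideal long-T1 limit is used, in which the ratio
    S2/S1 = (1 + n cos a)/(n + cos a) with n = TR2/TR1 — the closed form whose
    inversion the B1 reconstruction applies.  A finite T1 selects the exact
    interleaved steady state.
    """
    n = tr2_ms / tr1_ms
    ca, sa = np.cos(alpha_rad), np.sin(alpha_rad)
    if t1_ms is None:
        s1 = s0 * sa * (n + ca) / (n + 1.0)
        s2 = s0 * sa * (1.0 + n * ca) / (n + 1.0)
        return s1, s2
    e1 = np.exp(-tr1_ms / t1_ms)
    e2 = np.exp(-tr2_ms / t1_ms)
    den = 1.0 - e1 * e2 * ca**2
    s1 = s0 * sa * (1.0 - e2 + (1.0 - e1) * e2 * ca) / den
    s2 = s0 * sa * (1.0 - e1 + (1.0 - e2) * e1 * ca) / den
    return s1, s2


def _wrap_phase(phi):
    return np.angle(np.exp(1j * np.asarray(phi)))


def generate_field_series(
    spec: PhantomSpec, acq: AcquisitionSpec, truth: GroundTruth, mode: str
) -> dict:
    """Simulate one gantry angle of the B0 (dual-echo) or B1 (dual-TR) series.

    b0_dual_echo: returns magnitude + wrapped-phase volumes per echo, with
    phase = 2*pi*f*TE inside the cylinder; flags wrapping when the truth field
    exceeds the unambiguous range 1/(2*dTE).

    b1_dual_tr: returns the two magnitude volumes of the dual-TR sequence at
    actual flip angle = b1_fraction * nominal.
    """
    if spec.kind != "cylinder":
        raise InvalidSpecError("spec.kind must be 'cylinder'")
    diameter = spec.geom("cylinder_diameter_mm", 400.0)
    vol0 = _blank(acq)
    x, y, _ = vol0.coordinate_grids()
    x2, y2 = x[:, :, 0], y[:, :, 0]
    hx, hy = vol0.spacing_mm[0], vol0.spacing_mm[1]
    body = _circle_coverage(x2, y2, 0.0, 0.0, diameter / 2.0, 0.5 * (hx + hy))
    rng = truth.rng()
    out = {"gantry_angle_deg": acq.gantry_angle_deg}

    if mode == "b0_dual_echo":
        tes = list(acq.te_ms_list) or [5.4, 6.9]
        if len(tes) < 2:
            raise InvalidSpecError("b0 mode needs two echo times")
        f_hz = truth.eval_b0(x2, y2, acq.gantry_angle_deg)
        dte_s = abs(tes[1] - tes[0]) * 1e-3
        wrap = bool(np.any(np.abs(f_hz[body > 0.5]) > 1.0 / (2.0 * dte_s))) if dte_s else False
        for i, te in enumerate(tes[:2], start=1):
            sig = spec.object_signal * body
            phi = 2.0 * np.pi * f_hz * te * 1e-3
            re = sig * np.cos(phi) + rng.normal(0, truth.noise_sd, sig.shape) if truth.noise_sd else sig * np.cos(phi)
            im = sig * np.sin(phi) + rng.normal(0, truth.noise_sd, sig.shape) if truth.noise_sd else sig * np.sin(phi)
            mag, ph = np.hypot(re, im), np.arctan2(im, re)
            mvol, pvol = _blank(acq), _blank(acq)
            mvol.voxels[:, :, 0] = mag
            pvol.voxels[:, :, 0] = ph
            pvol.is_phase = True
            mvol.flags["te_ms"] = pvol.flags["te_ms"] = te
            out[f"magnitude_te{i}"], out[f"phase_te{i}"] = mvol, pvol
        out["wrap_warning"] = wrap
    elif mode == "b1_dual_tr":
        trs = spec.geometry.get("tr_pair_ms", (30.0, 150.0))
        nominal = acq.flip_angles_deg[0] if acq.flip_angles_deg else 60.0
        alpha = np.radians(nominal) * truth.eval_b1(x2, y2)
        s1, s2 = afi_signal_pair(alpha, trs[0], trs[1], t1_ms=spec.geometry.get("t1_ms"))
        for name, s, tr in (("tr1", s1, trs[0]), ("tr2", s2, trs[1])):
            v = _blank(acq)
            v.voxels[:, :, 0] = add_rician_noise(spec.object_signal * body * s, truth.noise_sd, rng)
            v.flags["tr_ms"] = tr
            v.flags["nominal_fa_deg"] = nominal
            out[name] = v
    else:
        raise InvalidSpecError(f"unknown field-series mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# Quantitative-MRI vial series (VFA / MESE / DWI)
# ---------------------------------------------------------------------------

def default_relaxometry_vials(n: int = 14, radius_mm: float = 60.0, diameter_mm: float = 20.0):
    """A 14-vial relaxometry layout on a circle.

    T1 spans 500-2000 ms (the design range of the two-point VFA protocol);
    T2 spans 40-200 ms, the tissue-relevant range an 8-echo train with
    TE = 22..99 ms can constrain (roughly up to twice the last echo time).
    T1 > T2 holds for every vial.
    """
    ang = 2 * np.pi * np.arange(n) / n
    centers = np.column_stack([radius_mm * np.cos(ang), radius_mm * np.sin(ang)])
    t1 = np.geomspace(500.0, 2000.0, n)
    t2 = np.geomspace(40.0, 200.0, n)
    return centers, diameter_mm, t1.tolist(), t2.tolist()


def default_diffusion_vials(diameter_mm: float = 16.0):
    """A 13-vial diffusion layout: center vial + inner and outer rings of six,
    each ring covering the full ADC range (mm^2/s).

    Nominal values follow the polyvinylpyrrolidone (PVP) concentration series
    0-50% at 0 degrees C, spanning ~0.13-1.1 x 10^-3 mm^2/s.
    """
    adcs = [1.1e-3, 0.82e-3, 0.59e-3, 0.40e-3, 0.25e-3, 0.13e-3]
    centers = [(0.0, 0.0)]
    rings = [0]
    for ring, radius in ((1, 30.0), (2, 62.0)):
        ang = 2 * np.pi * np.arange(6) / 6 + (0.0 if ring == 1 else np.pi / 6)
        centers += [(radius * np.cos(a), radius * np.sin(a)) for a in ang]
        rings += [ring] * 6
    adc = [1.1e-3] + adcs + adcs
    return np.array(centers), diameter_mm, adc, rings


def _vial_signal_map(spec, vol, per_vial_values, fn):
    x, y, _ = vol.coordinate_grids()
    x2, y2 = x[:, :, 0], y[:, :, 0]
    hx, hy = vol.spacing_mm[0], vol.spacing_mm[1]
    centers = np.asarray(spec.geometry["vial_centers_mm"], dtype=float)
    dia = spec.geom("vial_diameter_mm", 20.0)
    img = np.zeros((x2.shape[0], y2.shape[1]))
    for c, val in zip(centers, per_vial_values):
        cov = _circle_coverage(x2, y2, c[0], c[1], dia / 2.0, 0.5 * (hx + hy))
        img += cov * fn(val)
    return img


def noise_sd_for_image_snr(
    spec: PhantomSpec, acq: AcquisitionSpec, truth: GroundTruth, mode: str, snr: float
) -> float:
    """Noise SD giving a target image SNR for a qMRI series.

    Image SNR is defined on the acquired images: the mean signal inside the
    vials, averaged over the (non-dummy) volumes of the series, divided by
    the per-channel noise SD.
    """
    import dataclasses as _dc

    clean = _dc.replace(truth, noise_sd=0.0)
    vols = generate_qmri_series(spec, acq, clean, mode)
    vols = [v for v in vols if not v.flags.get("dummy")]
    centers = np.asarray(spec.geometry["vial_centers_mm"], dtype=float)
    dia = spec.geom("vial_diameter_mm", 20.0)
    x, y, _ = vols[0].coordinate_grids()
    x2, y2 = x[:, :, 0], y[:, :, 0]
    inside = np.zeros((x2.shape[0], y2.shape[1]), dtype=bool)
    for c in centers:
        inside |= np.hypot(x2 - c[0], y2 - c[1]) <= 0.4 * dia
    mean_sig = float(np.mean([v.voxels[:, :, 0][inside].mean() for v in vols]))
    return mean_sig / snr


def generate_qmri_series(
    spec: PhantomSpec, acq: AcquisitionSpec, truth: GroundTruth, mode: str
) -> list:
    """Simulate a quantitative-MRI vial series.

    vfa : one spoiled gradient-echo volume per flip angle (Ernst equation).
    mese: mono-exponential T2 decay per echo; a dummy first echo at
          TE_1 - dTE carrying a +5% stimulated-echo-like bias is prepended and
          flagged ``dummy`` for discard.
    dwi : mono-exponential diffusion decay per b-value.
    """
    if spec.kind != "vial_array":
        raise InvalidSpecError("spec.kind must be 'vial_array'")
    rng = truth.rng()
    s0 = spec.object_signal
    vols = []
    if mode == "vfa":
        fas = list(acq.flip_angles_deg)
        if len(set(fas)) < 2:
            raise InsufficientSeriesError("VFA needs >= 2 distinct flip angles")
        for fa in fas:
            v = _blank(acq)
            a = np.radians(fa)
            img = _vial_signal_map(spec, v, truth.t1_ms, lambda t1, a=a: spgr_signal(a, acq.tr_ms, t1, s0))
            v.voxels[:, :, 0] = add_rician_noise(img, truth.noise_sd, rng)
            v.flags.update(flip_angle_deg=fa, tr_ms=acq.tr_ms)
            vols.append(v)
    elif mode == "mese":
        tes = list(acq.te_ms_list)
        if len(tes) < 2:
            raise InsufficientSeriesError("MESE needs >= 2 echoes")
        dte = tes[1] - tes[0]
        dummy_bias = spec.geometry.get("dummy_echo_bias", 0.05)
        all_tes = [max(tes[0] - dte, tes[0] / 2.0)] + tes
        for i, te in enumerate(all_tes):
            v = _blank(acq)
            gain = (1.0 + dummy_bias) if i == 0 else 1.0
            img = _vial_signal_map(
                spec, v, truth.t2_ms, lambda t2, te=te, g=gain: g * s0 * np.exp(-te / t2)
            )
            v.voxels[:, :, 0] = add_rician_noise(img, truth.noise_sd, rng)
            v.flags.update(te_ms=te, dummy=(i == 0))
            vols.append(v)
    elif mode == "dwi":
        bvals = list(acq.b_values_s_per_mm2)
        if len(set(bvals)) < 2:
            raise InsufficientSeriesError("DWI needs >= 2 b-values")
        for b in bvals:
            v = _blank(acq)
            img = _vial_signal_map(
                spec, v, truth.adc_mm2_per_s, lambda adc, b=b: s0 * np.exp(-b * adc)
            )
            v.voxels[:, :, 0] = add_rician_noise(img, truth.noise_sd, rng)
            v.flags.update(b_value=b)
            vols.append(v)
    else:
        raise InvalidSpecError(f"unknown qmri mode {mode!r}")
    return vols
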