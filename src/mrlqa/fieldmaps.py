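"""B0/B1 field-map reconstruction and gantry-angle analysis.

B0 is reconstructed from a dual-echo phase pair as
``f = wrap(phi2 - phi1) / (2 pi dTE)`` (unambiguous within +-1/(2 dTE)) and
expressed both in Hz and in ppm of the nominal resonance frequency.  B1 is
reconstructed from the dual-TR magnitude pair through the long-T1 ratio
inversion ``alpha = arccos((r n - 1)/(n - r))`` with ``r = S(TR2)/S(TR1)``
and ``n = TR2/TR1``, expressed as percent of the nominal flip angle.

The gantry sweep subtracts the voxelwise mean map across all angles from
each B0 map to remove the static (shim) contribution, and reports the
peak-to-peak range inside a 35-cm ROI per angle both raw and
mean-subtracted.  For B1 the per-angle mean absolute deviation from nominal
is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GAMMA_MHZ_PER_T, ImageVolume, InvalidSpecError, RoiSpec

__all__ = [
    "FieldMap",
    "GantrySweep",
    "reconstruct_b0",
    "reconstruct_b1",
    "analyze_gantry_sweep",
    "b0_distortion_estimate",
    "DEFAULT_ROI",
]

#: analysis region: 35-cm-diameter circle at the phantom center
DEFAULT_ROI = RoiSpec(shape="circle", center_mm=(0.0, 0.0), diameter_mm=350.0)


@dataclass
class FieldMap:
    """Per-voxel B0 (Hz, with a derived ppm channel) or B1 (percent of
    nominal flip angle) map at one gantry angle."""

    values: np.ndarray  # Hz for B0; percent for B1
    kind: str  # "b0" | "b1"
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    gantry_angle_deg: float = 0.0
    roi: RoiSpec = field(default_factory=lambda: DEFAULT_ROI)
    f0_MHz: float = GAMMA_MHZ_PER_T * 1.5
    valid: np.ndarray = None  # mask of reconstructable voxels
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)

    @property
    def ppm(self) -> np.ndarray:
        if self.kind != "b0":
            raise InvalidSpecError("ppm channel only exists for B0 maps")
        return self.values / self.f0_MHz

    def _vol(self) -> ImageVolume:
        return ImageVolume(self.values, self.spacing_mm, self.origin_mm)

    def roi_mask(self) -> np.ndarray:
        return self.roi.mask(self._vol()) & self.valid

    def roi_values(self) -> np.ndarray:
        return self.values[self.roi_mask()]


@dataclass
class GantrySweep:
    """Gantry-resolved field statistics over a common grid and ROI."""

    angles_deg: list
    kind: str
    mean_map: np.ndarray
    residual_maps: list  # per-angle map minus voxelwise mean (b0 only)
    peak_to_peak_hz: dict  # per angle, mean-subtracted (b0)
    peak_to_peak_ppm: dict
    raw_peak_to_peak_hz: dict
    raw_peak_to_peak_ppm: dict
    b1_mean_abs_deviation_percent: dict
    b1_grand_mean_percent: float = None
    b1_grand_sd_percent: float = None


def _phase_of(vol: ImageVolume) -> np.ndarray:
    if not vol.is_phase:
        raise InvalidSpecError("expected a phase volume (radians, wrapped)")
    return vol.voxels


def reconstruct_b0(
    echo1: ImageVolume,
    echo2: ImageVolume,
    te1_ms: float,
    te2_ms: float,
    gantry_angle_deg: float = 0.0,
    roi: RoiSpec = None,
    f0_MHz: float = GAMMA_MHZ_PER_T * 1.5,
    unwrap: bool = False,
) -> FieldMap:
    """Off-resonance map from a dual-echo phase pair.

    f = wrap(phi2 - phi1)/(2 pi dTE); values alias outside +-1/(2 dTE)
    (+-333.3 Hz at dTE = 1.5 ms) — a ``wrap_limit_hz`` flag records the
    unambiguous range.  QA fields sit well inside that range, so no
    unwrapping is applied by default; ``unwrap=True`` runs a quality-guided
    spatial unwrapper on the phase difference for injected large offsets
    (correct up to a global multiple of 1/dTE).
    """
    dte_s = (te2_ms - te1_ms) * 1e-3
    if dte_s == 0:
        raise InvalidSpecError("echo-time difference must be non-zero")
    dphi = np.angle(np.exp(1j * (_phase_of(echo2) - _phase_of(echo1))))
    if unwrap:
        from skimage.restoration import unwrap_phase

        dphi = np.stack(
            [np.asarray(unwrap_phase(dphi[:, :, k])) for k in range(dphi.shape[2])],
            axis=2,
        )
    f_hz = dphi / (2.0 * np.pi * dte_s)
    fm = FieldMap(
        f_hz,
        "b0",
        echo1.spacing_mm,
        echo1.origin_mm,
        gantry_angle_deg=gantry_angle_deg,
        f0_MHz=f0_MHz,
    )
    if roi is not None:
        fm.roi = roi
    fm.flags["wrap_limit_hz"] = abs(1.0 / (2.0 * dte_s))
    return fm


def reconstruct_b1(
    s_tr1: ImageVolume,
    s_tr2: ImageVolume,
    tr1_ms: float,
    tr2_ms: float,
    nominal_fa_deg: float,
    gantry_angle_deg: float = 0.0,
    roi: RoiSpec = None,
) -> FieldMap:
    """Actual-flip-angle map from the dual-TR magnitude pair, as percent of
    the nominal flip angle.

    Uses the long-T1 ratio inversion alpha = arccos((r n - 1)/(n - r)); the
    ratio is only invertible for r in (1/n, 1) — voxels outside that domain
    (background, extreme noise) are masked and counted in
    ``flags['n_masked']``.
    """
    if not (tr2_ms > tr1_ms > 0):
        raise InvalidSpecError("need TR2 > TR1 > 0")
    n = tr2_ms / tr1_ms
    with np.errstate(divide="ignore", invalid="ignore"):
        r = s_tr2.voxels / s_tr1.voxels
        cos_a = (r * n - 1.0) / (n - r)
    valid = np.isfinite(cos_a) & (r > 1.0 / n) & (r < 1.0)
    alpha = np.full_like(cos_a, np.nan)
    alpha[valid] = np.degrees(np.arccos(np.clip(cos_a[valid], -1.0, 1.0)))
    fm = FieldMap(
        100.0 * alpha / nominal_fa_deg,
        "b1",
        s_tr1.spacing_mm,
        s_tr1.origin_mm,
        gantry_angle_deg=gantry_angle_deg,
        valid=valid,
    )
    if roi is not None:
        fm.roi = roi
    fm.flags["n_masked"] = int((~valid).sum())
    return fm


def _ptp(values: np.ndarray, percentiles=(0.0, 100.0)) -> float:
    lo, hi = np.percentile(values, percentiles)
    return float(hi - lo)


def analyze_gantry_sweep(maps: list, mode: str, percentiles=(0.0, 100.0)) -> GantrySweep:
    """Gantry-dependence statistics over a stack of field maps.

    b0: subtract the voxelwise mean across angles from each map and report
    the per-angle ROI peak-to-peak (range by default; percentile pair
    configurable) in Hz and ppm, alongside the raw (non-subtracted) values.
    b1: per-angle mean |deviation from 100%| plus the grand mean +- SD.
    """
    if len(maps) < 2:
        raise InvalidSpecError("a gantry sweep needs at least two angles")
    shape = maps[0].values.shape
    if any(m.values.shape != shape for m in maps):
        raise InvalidSpecError("all maps in a sweep must share one grid")
    if any(m.kind != mode for m in maps):
        raise InvalidSpecError(f"sweep mode {mode!r} does not match map kinds")
    angles = [m.gantry_angle_deg for m in maps]
    stack = np.stack([m.values for m in maps])
    mean_map = stack.mean(axis=0)

    ptp_hz, ptp_ppm, raw_hz, raw_ppm, b1dev = {}, {}, {}, {}, {}
    residuals = []
    for m in maps:
        mask = m.roi_mask()
        if mode == "b0":
            res = m.values - mean_map
            residuals.append(res)
            ptp_hz[m.gantry_angle_deg] = _ptp(res[mask], percentiles)
            ptp_ppm[m.gantry_angle_deg] = _ptp(res[mask] / m.f0_MHz, percentiles)
            raw_hz[m.gantry_angle_deg] = _ptp(m.values[mask], percentiles)
            raw_ppm[m.gantry_angle_deg] = _ptp(m.values[mask] / m.f0_MHz, percentiles)
        else:
            b1dev[m.gantry_angle_deg] = float(np.mean(np.abs(m.values[mask] - 100.0)))
    gm = gsd = None
    if mode == "b1":
        devs = np.array(list(b1dev.values()))
        gm, gsd = float(devs.mean()), float(devs.std(ddof=1)) if len(devs) > 1 else 0.0
    return GantrySweep(
        angles_deg=angles,
        kind=mode,
        mean_map=mean_map,
        residual_maps=residuals,
        peak_to_peak_hz=ptp_hz,
        peak_to_peak_ppm=ptp_ppm,
        raw_peak_to_peak_hz=raw_hz,
        raw_peak_to_peak_ppm=raw_ppm,
        b1_mean_abs_deviation_percent=b1dev,
        b1_grand_mean_percent=gm,
        b1_grand_sd_percent=gsd,
    )


def b0_distortion_estimate(delta_b0_ppm: float, field_T: float, g_read_mT_per_m: float) -> float:
    """Worst-case geometric displacement (mm) from a B0 inhomogeneity read
    out at gradient strength G_read: displacement = dB0 / G_read.

    A 3 ppm inhomogeneity at 1.5 T read at 15 mT/m displaces by 0.30 mm.
    """
    if g_read_mT_per_m == 0:
        raise ZeroDivisionError("readout gradient must be non-zero")
    if delta_b0_ppm < 0 or field_T <= 0 or g_read_mT_per_m < 0:
        raise InvalidSpecError("inputs must be positive")
    db0_T = delta_b0_ppm * 1e-6 * field_T
    g_T_per_m = g_read_mT_per_m * 1e-3
    return db0_T / g_T_per_m * 1000.0  # m -> mm
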