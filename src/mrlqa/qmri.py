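"""Quantitative T1/T2/ADC estimation and bias/reproducibility statistics.

T1 comes from the variable-flip-angle (VFA) spoiled gradient-echo series via
the linearized form S/sin(a) = E1 * S/tan(a) + S0 (1 - E1) solved voxelwise
by ordinary least squares; T2 and ADC come from log-linear least squares on
the mono-exponential decays S(TE) = S0 exp(-TE/T2) and
S(b) = S0 exp(-b ADC).  ROI statistics follow the phantom-QA conventions:
bias B = (measured - nominal)/nominal x 100% and reproducibility
COV = sigma/mu x 100% of the per-session ROI means.

The flip-angle design helper implements the fractional-signal criterion:
the two flip angles at which the spoiled steady-state signal falls to a
fraction (default 0.71) of its Ernst-angle maximum are the optimal pair for
two-point VFA T1 mapping.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import ImageVolume, InvalidSpecError, RoiSpec
from .phantoms import InsufficientSeriesError, spgr_signal

__all__ = [
    "QMRIFitResult",
    "VialReport",
    "EmptyFitError",
    "fit_t1_vfa",
    "optimal_vfa_angles",
    "fit_t2_mese",
    "fit_adc",
    "vial_report",
    "rank_dependence_tests",
]


class EmptyFitError(ValueError):
    """Every voxel of the requested region was masked."""


@dataclass
class QMRIFitResult:
    """Per-voxel parameter map with fit diagnostics."""

    parameter: np.ndarray  # T1 ms / T2 ms / ADC mm^2/s; NaN where masked
    s0: np.ndarray
    r_squared: np.ndarray
    mask: np.ndarray  # True where the fit is valid
    kind: str = ""
    spacing_mm: np.ndarray = None
    origin_mm: np.ndarray = None

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.parameter, self.spacing_mm, self.origin_mm)


@dataclass
class VialReport:
    """Per-vial ROI statistics across sessions."""

    nominal: list
    session_means: np.ndarray  # (n_vials, n_sessions)
    session_sds: np.ndarray
    bias_percent: list
    cov_percent: list  # None entries when < 2 sessions
    median_bias_percent: float
    bias_range_percent: tuple
    median_cov_percent: float = None
    cov_range_percent: tuple = None


def _stack(series: list) -> np.ndarray:
    shapes = {v.voxels.shape for v in series}
    if len(shapes) != 1:
        raise InvalidSpecError("all volumes of a series must share one grid")
    return np.stack([v.voxels for v in series])


def _ols_1d(x: np.ndarray, Y: np.ndarray):
    """Row-wise OLS of Y (n_obs, n_vox) on x (n_obs,): slope, intercept, R^2."""
    xm = x.mean()
    ym = Y.mean(axis=0)
    xc = x - xm
    yc = Y - ym
    sxx = float(np.dot(xc, xc))
    sxy = xc @ yc
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = ((yc - np.outer(xc, slope)) ** 2).sum(axis=0)
    ss_tot = (yc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return slope, intercept, r2


def fit_t1_vfa(
    series: list,
    flip_angles_deg: list,
    tr_ms: float,
    r2_threshold: float = 0.95,
    method: str = "linear",
) -> QMRIFitResult:
    """Voxelwise VFA T1 fit on the linearized spoiled steady-state equation.

    Per voxel, y_i = S_i/sin(a_i) is regressed on x_i = S_i/tan(a_i); the
    slope is E1 = exp(-TR/T1), so T1 = -TR/ln(E1) and S0 = intercept/(1-E1).
    Voxels with E1 outside (0, 1) or a poor linear fit are masked.
    ``method="nonlinear"`` refines the linear solution with damped
    Gauss-Newton steps on the untransformed signal equation (useful when
    the log-domain noise weighting of the linear form matters).
    """
    if method not in ("linear", "nonlinear"):
        raise InvalidSpecError(f"unknown VFA method {method!r}")
    fas = np.asarray(flip_angles_deg, dtype=float)
    if len(set(fas.tolist())) < 2:
        raise InsufficientSeriesError("VFA fit needs >= 2 distinct flip angles")
    if len(series) != len(fas):
        raise InvalidSpecError("one volume per flip angle required")
    S = _stack(series)
    a = np.radians(fas).reshape(-1, *([1] * (S.ndim - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        y = S / np.sin(a)
        x = S / np.tan(a)
    shp = S.shape[1:]
    nvox = int(np.prod(shp))
    # voxelwise regression with per-voxel x requires the generic form
    X = x.reshape(len(fas), nvox)
    Y = y.reshape(len(fas), nvox)
    xm = X.mean(axis=0)
    ym = Y.mean(axis=0)
    xc = X - xm
    yc = Y - ym
    sxx = (xc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (xc * yc).sum(axis=0) / sxx
        intercept = ym - slope * xm
        ss_res = ((yc - xc * slope) ** 2).sum(axis=0)
        ss_tot = (yc**2).sum(axis=0)
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        # two-point fits are exact; guard the 0/0 case
        if len(fas) == 2:
            r2 = np.where(np.isfinite(slope), 1.0, 0.0)
    valid = np.isfinite(slope) & (slope > 0.0) & (slope < 1.0) & (sxx > 0)
    valid &= r2 >= r2_threshold
    # a signal with no flip-angle dependence carries no T1 information even
    # though two points always fit a line exactly
    S2 = S.reshape(len(fas), nvox)
    valid &= ~np.all(S2 == S2[0], axis=0)
    t1 = np.full(nvox, np.nan)
    s0 = np.full(nvox, np.nan)
    t1[valid] = -tr_ms / np.log(slope[valid])
    s0[valid] = intercept[valid] / (1.0 - slope[valid])
    if method == "nonlinear" and valid.any():
        e1, s0v = _vfa_gauss_newton(
            S.reshape(len(fas), nvox)[:, valid], np.radians(fas),
            slope[valid], s0[valid],
        )
        ok = (e1 > 0.0) & (e1 < 1.0) & np.isfinite(e1)
        t1_ref = np.full(ok.shape, np.nan)
        t1_ref[ok] = -tr_ms / np.log(e1[ok])
        t1[valid] = np.where(ok, t1_ref, t1[valid])
        s0[valid] = np.where(ok, s0v, s0[valid])
    return QMRIFitResult(
        t1.reshape(shp), s0.reshape(shp), r2.reshape(shp), valid.reshape(shp),
        kind="t1_ms", spacing_mm=series[0].spacing_mm, origin_mm=series[0].origin_mm,
    )


def _vfa_gauss_newton(S, alphas, e1, s0, n_iter: int = 25, damping: float = 0.5):
    """Damped Gauss-Newton refinement of (E1, S0) per voxel on the spoiled
    steady-state signal equation, vectorized over voxels."""
    sa = np.sin(alphas)[:, None]
    ca = np.cos(alphas)[:, None]
    e1 = e1.copy()
    s0 = s0.copy()
    for _ in range(n_iter):
        den = 1.0 - e1[None, :] * ca
        model = s0[None, :] * sa * (1.0 - e1[None, :]) / den
        r = S - model
        j_s0 = model / s0[None, :]
        j_e1 = s0[None, :] * sa * (ca - 1.0) / den**2
        # solve the per-voxel 2x2 normal equations
        a11 = (j_s0 * j_s0).sum(0)
        a12 = (j_s0 * j_e1).sum(0)
        a22 = (j_e1 * j_e1).sum(0)
        b1 = (j_s0 * r).sum(0)
        b2 = (j_e1 * r).sum(0)
        det = a11 * a22 - a12**2
        det = np.where(np.abs(det) > 1e-300, det, np.nan)
        ds0 = (b1 * a22 - b2 * a12) / det
        de1 = (b2 * a11 - b1 * a12) / det
        s0 = s0 + damping * np.nan_to_num(ds0)
        e1 = np.clip(e1 + damping * np.nan_to_num(de1), 1e-9, 1.0 - 1e-9)
    return e1, s0


def design_vfa_pair(
    t1_range_ms=(1000.0, 2000.0),
    tr_ms: float = 20.0,
    signal_fraction: float = 0.71,
    method: str = "midpoint",
) -> tuple:
    """Flip-angle pair for a T1 design range.

    ``midpoint`` evaluates the two-root criterion at the center of the
    range (reproduces the clinical {4, 22} deg pair for 1000-2000 ms at
    TR = 20 ms); ``average`` computes the pair at each bound and averages
    the lower and upper members.
    """
    lo_t1, hi_t1 = t1_range_ms
    if method == "midpoint":
        return optimal_vfa_angles((lo_t1 + hi_t1) / 2.0, tr_ms, signal_fraction)
    if method == "average":
        a = optimal_vfa_angles(lo_t1, tr_ms, signal_fraction)
        b = optimal_vfa_angles(hi_t1, tr_ms, signal_fraction)
        return ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
    raise InvalidSpecError(f"unknown design method {method!r}")


def optimal_vfa_angles(
    t1_ms: float, tr_ms: float, signal_fraction: float = 0.71
) -> tuple:
    """Optimal two-point VFA flip angles (degrees) by the fractional-signal
    criterion.

    The spoiled steady-state signal peaks at the Ernst angle
    theta_E = arccos(exp(-TR/T1)); the returned pair are the two roots of
    S(alpha) = signal_fraction * S(theta_E), bracketed on (0, theta_E) and
    (theta_E, 90 deg).
    """
    if t1_ms <= 0 or tr_ms <= 0:
        raise InvalidSpecError("T1 and TR must be positive")
    if not (0.0 < signal_fraction < 1.0):
        raise InvalidSpecError("signal_fraction must lie in (0, 1)")
    e1 = math.exp(-tr_ms / t1_ms)
    theta_e = math.acos(e1)
    target = signal_fraction * spgr_signal(theta_e, tr_ms, t1_ms)

    def g(a):
        return spgr_signal(a, tr_ms, t1_ms) - target

    eps = 1e-9
    if not (g(eps) < 0 < g(theta_e)) or not (g(math.pi / 2) < 0):
        raise RuntimeError("no bracketing sign change for the requested fraction")
    lo = optimize.brentq(g, eps, theta_e, xtol=1e-12)
    hi = optimize.brentq(g, theta_e, math.pi / 2, xtol=1e-12)
    return math.degrees(lo), math.degrees(hi)


def _loglinear_fit(series, abscissa, kind, r2_threshold):
    S = _stack(series)
    x = np.asarray(abscissa, dtype=float)
    shp = S.shape[1:]
    nvox = int(np.prod(shp))
    pos = np.all(S > 0, axis=0).reshape(nvox)
    Y = np.where(S > 0, np.log(np.where(S > 0, S, 1.0)), np.nan).reshape(len(x), nvox)
    slope, intercept, r2 = _ols_1d(x, Y)
    if len(x) == 2:
        r2 = np.where(np.isfinite(slope), 1.0, 0.0)
    valid = pos & np.isfinite(slope) & (slope < 0) & (r2 >= r2_threshold)
    param = np.full(nvox, np.nan)
    s0 = np.full(nvox, np.nan)
    if kind == "t2_ms":
        param[valid] = -1.0 / slope[valid]
    else:  # adc
        param[valid] = -slope[valid]
    s0[valid] = np.exp(intercept[valid])
    return QMRIFitResult(
        param.reshape(shp), s0.reshape(shp), r2.reshape(shp), valid.reshape(shp),
        kind=kind, spacing_mm=series[0].spacing_mm, origin_mm=series[0].origin_mm,
    )


def fit_t2_mese(
    series: list,
    te_ms_list: list = None,
    discard_first: bool = True,
    r2_threshold: float = 0.95,
) -> QMRIFitResult:
    """Voxelwise mono-exponential T2 fit: OLS of ln S on TE, T2 = -1/slope.

    ``discard_first`` (default) drops the first echo — the dummy echo
    contaminated by stimulated-echo pathways — before fitting.
    """
    if te_ms_list is None:
        te_ms_list = [v.flags.get("te_ms") for v in series]
    if any(t is None for t in te_ms_list):
        raise InvalidSpecError("echo times required (argument or volume flags)")
    series, tes = list(series), list(te_ms_list)
    if discard_first:
        series, tes = series[1:], tes[1:]
    if len(series) < 2:
        raise InsufficientSeriesError("T2 fit needs >= 2 usable echoes")
    res = _loglinear_fit(series, tes, "t2_ms", r2_threshold)
    if not res.mask.any():
        raise EmptyFitError("all voxels masked in T2 fit")
    return res


def fit_adc(series: list, b_values: list = None, r2_threshold: float = 0.95) -> QMRIFitResult:
    """Voxelwise mono-exponential diffusion fit: OLS of ln S on b, ADC = -slope
    (mm^2/s when b is in s/mm^2)."""
    if b_values is None:
        b_values = [v.flags.get("b_value") for v in series]
    if any(b is None for b in b_values):
        raise InvalidSpecError("b-values required (argument or volume flags)")
    if len(set(b_values)) < 2:
        raise InsufficientSeriesError("ADC fit needs >= 2 distinct b-values")
    res = _loglinear_fit(series, b_values, "adc_mm2_per_s", r2_threshold)
    if not res.mask.any():
        raise EmptyFitError("all voxels masked in ADC fit")
    return res


def _roi_stats(result: QMRIFitResult, center_mm, roi_diameter_mm):
    vol = result.as_volume()
    roi = RoiSpec(shape="circle", center_mm=tuple(center_mm), diameter_mm=roi_diameter_mm)
    mask = roi.mask(vol) & result.mask & np.isfinite(result.parameter)
    vals = result.parameter[mask]
    if vals.size == 0:
        raise EmptyFitError(f"ROI at {center_mm} contains no valid voxels")
    return float(vals.mean()), float(vals.std(ddof=0))


def vial_report(
    results: list,
    vial_nominals: list,
    roi_centers_mm: list,
    roi_diameter_mm: float = 10.0,
    cov_ddof: int = 0,
) -> VialReport:
    """Bias and reproducibility statistics per vial across sessions.

    ``results`` is one :class:`QMRIFitResult` per session.  Per vial the ROI
    (1-cm-diameter circle at the vial center) mean is taken per session;
    bias compares the across-session mean with the nominal value and COV is
    the SD/mean of the session means (population SD by default;
    ``cov_ddof=1`` selects the sample convention).  With a single session
    COV is reported as None, never 0.
    """
    if len(results) < 1:
        raise InvalidSpecError("at least one session required")
    nv = len(vial_nominals)
    if len(roi_centers_mm) != nv:
        raise InvalidSpecError("one ROI center per vial required")
    means = np.empty((nv, len(results)))
    sds = np.empty_like(means)
    for s, res in enumerate(results):
        for v, c in enumerate(roi_centers_mm):
            means[v, s], sds[v, s] = _roi_stats(res, c, roi_diameter_mm)
    bias = [
        float((means[v].mean() - vial_nominals[v]) / vial_nominals[v] * 100.0)
        for v in range(nv)
    ]
    if len(results) >= 2:
        cov = [
            float(means[v].std(ddof=cov_ddof) / means[v].mean() * 100.0) for v in range(nv)
        ]
        med_cov, cov_rng = float(np.median(cov)), (min(cov), max(cov))
    else:
        cov, med_cov, cov_rng = [None] * nv, None, None
    return VialReport(
        nominal=list(vial_nominals),
        session_means=means,
        session_sds=sds,
        bias_percent=bias,
        cov_percent=cov,
        median_bias_percent=float(np.median(bias)),
        bias_range_percent=(min(bias), max(bias)),
        median_cov_percent=med_cov,
        cov_range_percent=cov_rng,
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (n <= 8)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = _spearman_of_ranks(rx, ry[list(perm)])
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def _spearman_of_ranks(rx, ry):
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    den = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    return float((rxc * ryc).sum() / den) if den > 0 else np.nan


def rank_dependence_tests(report: VialReport, use_cov: bool = True, use_bias: bool = True) -> dict:
    """Spearman rank correlation of bias and COV against the measured value.

    Exact permutation p-values for n <= 8 vials, the large-sample
    approximation otherwise.  Degenerate (constant) inputs yield rho = NaN
    with a warning.
    """
    measured = report.session_means.mean(axis=1)
    n = len(measured)
    if n < 4:
        raise InvalidSpecError("rank tests need >= 4 vials")
    out = {}
    targets = {}
    if use_bias:
        targets["bias"] = np.asarray(report.bias_percent, dtype=float)
    if use_cov and report.cov_percent is not None and report.cov_percent[0] is not None:
        targets["cov"] = np.asarray(report.cov_percent, dtype=float)
    for name, yv in targets.items():
        if np.allclose(yv, yv[0]) or np.allclose(measured, measured[0]):
            warnings.warn(f"{name}: constant input, Spearman rho undefined")
            out[name] = {"spearman_rho": float("nan"), "p_value": float("nan")}
            continue
        rho = _spearman_of_ranks(stats.rankdata(measured), stats.rankdata(yv))
        if n <= 8:
            p = _exact_spearman_p(measured, yv, rho)
        else:
            p = float(stats.spearmanr(measured, yv).pvalue)
        out[name] = {"spearman_rho": float(rho), "p_value": float(p)}
    return out
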