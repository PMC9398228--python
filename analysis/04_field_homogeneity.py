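#!/usr/bin/env python
"""Gantry-resolved B0/B1 homogeneity on the 40-cm cylinder.

Simulates the 12-angle sweep (0..330 deg in 30-deg steps): a static shim
field whose in-ROI range is largest at gantry 180 deg (~3 ppm raw
peak-to-peak) plus small gantry-locked perturbations, and a B1 profile
sitting ~1.2% off nominal.  Reconstructs the maps from the dual-echo and
dual-TR series, subtracts the across-angle mean map from each B0
measurement, and tabulates raw and mean-subtracted peak-to-peak per angle.
Finally the worst raw inhomogeneity is converted into a worst-case
geometric displacement at the 15 mT/m readout gradient.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mrlqa.core import GAMMA_MHZ_PER_T, AcquisitionSpec
from mrlqa.fieldmaps import (
    analyze_gantry_sweep,
    b0_distortion_estimate,
    reconstruct_b0,
    reconstruct_b1,
)
from mrlqa.phantoms import GroundTruth, PhantomSpec, generate_field_series

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)
F0 = GAMMA_MHZ_PER_T * 1.5
ANGLES = list(range(0, 360, 30))

spec = PhantomSpec(kind="cylinder", object_signal=100.0)


def static_b0(x, y):
    # smooth shim residual (ppm x F0_MHz = Hz): quadratic bowl + linear
    # term, ~2.7 ppm range inside the 35-cm ROI
    return F0 * (2.4 * ((x / 175.0) ** 2 + 0.6 * (y / 175.0) ** 2) + 0.3 * x / 175.0)


def gantry_b0(x, y, angle):
    # gantry-locked perturbation an order of magnitude below the static
    # term, adding constructively at gantry 180 deg
    a = np.radians(angle)
    return F0 * 0.15 * (1.0 - np.cos(a)) * ((x / 175.0) ** 2 - 0.3 * (y / 175.0))


b0_maps, b1_maps = [], []
for ang in ANGLES:
    acq = AcquisitionSpec(tr_ms=30.0, te_ms_list=[5.4, 6.9], flip_angles_deg=[60.0],
                          voxel_size_mm=(3.0, 3.0, 10.0), matrix=(150, 150, 1),
                          gantry_angle_deg=float(ang))
    scale = 1.0 + 0.001 * np.cos(np.radians(ang))  # mild gantry dependence
    truth = GroundTruth(
        b0_field_hz=static_b0, b0_gantry_hz=gantry_b0,
        b1_fraction=lambda x, y, s=scale: s * (1.016 - 0.008 * (np.hypot(x, y) / 175.0) ** 2),
        noise_sd=0.2, seed=100 + ang)
    b0 = generate_field_series(spec, acq, truth, "b0_dual_echo")
    b0_maps.append(reconstruct_b0(b0["phase_te1"], b0["phase_te2"], 5.4, 6.9,
                                  gantry_angle_deg=ang))
    b1 = generate_field_series(spec, acq, truth, "b1_dual_tr")
    b1_maps.append(reconstruct_b1(b1["tr1"], b1["tr2"], 30.0, 150.0, 60.0,
                                  gantry_angle_deg=ang))

sb0 = analyze_gantry_sweep(b0_maps, "b0")
sb1 = analyze_gantry_sweep(b1_maps, "b1")

rows = [
    {
        "angle_deg": a,
        "b0_ptp_raw_ppm": round(sb0.raw_peak_to_peak_ppm[a], 4),
        "b0_ptp_mean_subtracted_ppm": round(sb0.peak_to_peak_ppm[a], 4),
        "b1_mean_abs_dev_percent": round(sb1.b1_mean_abs_deviation_percent[a], 3),
    }
    for a in ANGLES
]
pd.DataFrame(rows).to_csv(RESULTS / "field_homogeneity_by_angle.csv", index=False)

worst = max(sb0.raw_peak_to_peak_ppm, key=sb0.raw_peak_to_peak_ppm.get)
worst_ppm = sb0.raw_peak_to_peak_ppm[worst]
displacement = b0_distortion_estimate(worst_ppm, 1.5, 15.0)
summary = {
    "worst_raw_ptp_ppm": round(worst_ppm, 3),
    "worst_raw_ptp_angle_deg": worst,
    "max_mean_subtracted_ptp_ppm": round(max(sb0.peak_to_peak_ppm.values()), 3),
    "b1_grand_mean_deviation_percent": round(sb1.b1_grand_mean_percent, 3),
    "b1_grand_sd_percent": round(sb1.b1_grand_sd_percent, 3),
    "b0_displacement_mm_at_15mT_per_m": round(displacement, 3),
}
(RESULTS / "field_homogeneity_summary.json").write_text(
    json.dumps(summary, indent=1, sort_keys=True))

print(f"worst raw B0 peak-to-peak: {worst_ppm:.2f} ppm at gantry {worst} deg")
print(f"gantry-induced (mean-subtracted) peak-to-peak stays below "
      f"{max(sb0.peak_to_peak_ppm.values()):.2f} ppm — an order of magnitude smaller")
print(f"B1 deviation from nominal: {sb1.b1_grand_mean_percent:.2f} "
      f"+- {sb1.b1_grand_sd_percent:.2f} % across angles")
print(f"worst-case displacement at 15 mT/m readout: {displacement:.2f} mm")
print(f"wrote {RESULTS / 'field_homogeneity_by_angle.csv'}")
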