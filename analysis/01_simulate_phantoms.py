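#!/usr/bin/env python
"""Generate one instance of every synthetic QA phantom and archive the
volumes (NIfTI, under scratch/) plus a ground-truth manifest (results/).

The four phantom classes drive the downstream analyses:
image-quality phantom sections (grid / wedge pair / edge), the 7-plate
1932-marker fiducial grid, the 40-cm field-mapping cylinder, and the
relaxometry/diffusion vial arrays.
"""

import json
from pathlib import Path

import numpy as np

from mrlqa.core import AcquisitionSpec, save_nifti
from mrlqa.phantoms import (
    GroundTruth,
    PhantomSpec,
    default_diffusion_vials,
    default_relaxometry_vials,
    fiducial_grid_positions,
    generate_fiducial_volume,
    generate_piqt_images,
    generate_qmri_series,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"
SEED = 20210104

manifest = {"seed": SEED, "volumes": []}
SCRATCH.mkdir(parents=True, exist_ok=True)
RESULTS.mkdir(exist_ok=True)

truth = GroundTruth(noise_sd=2.0, seed=SEED)
for kind in ("piqt_grid", "piqt_wedge", "piqt_edge"):
    spec = PhantomSpec(kind=kind, object_signal=100.0)
    vol = generate_piqt_images(spec, AcquisitionSpec(), truth)["magnitude"]
    p = save_nifti(vol, SCRATCH / f"{kind}.nii")
    manifest["volumes"].append({"kind": kind, "path": str(p.relative_to(ROOT)),
                                "noise_sd": 2.0})
    print(f"{kind:12s}: matrix {vol.shape}, voxel {tuple(vol.spacing_mm)} mm")

fspec = PhantomSpec(kind="fiducial3d", object_signal=100.0)
fvol, known = generate_fiducial_volume(fspec, GroundTruth(seed=SEED))
save_nifti(fvol, SCRATCH / "fiducial3d.nii")
np.savetxt(SCRATCH / "known_markers_mm.csv", known, delimiter=",",
           header="x_mm,y_mm,z_mm", comments="")
print(f"fiducial3d  : {len(known)} markers on "
      f"{len(np.unique(known[:, 2]))} plates, matrix {fvol.shape}")
manifest["volumes"].append({"kind": "fiducial3d", "n_markers": int(len(known)),
                            "plate_spacing_mm": 55.0, "inplane_spacing_mm": 25.0})

centers, dia, t1s, t2s = default_relaxometry_vials()
dcenters, ddia, adcs, rings = default_diffusion_vials()
manifest["relaxometry_vials"] = {"t1_ms": t1s, "t2_ms": t2s,
                                 "centers_mm": centers.tolist(), "diameter_mm": dia}
manifest["diffusion_vials"] = {"adc_mm2_per_s": adcs, "rings": rings,
                               "centers_mm": dcenters.tolist(), "diameter_mm": ddia}
spec = PhantomSpec(kind="vial_array", object_signal=1000.0,
                   geometry={"vial_centers_mm": centers.tolist(), "vial_diameter_mm": dia})
acq = AcquisitionSpec(tr_ms=20.0, te_ms_list=[2.3], flip_angles_deg=[4.0, 22.0],
                      voxel_size_mm=(2.0, 2.0, 3.0), matrix=(160, 160, 1))
for v in generate_qmri_series(spec, acq, GroundTruth(t1_ms=t1s, t2_ms=t2s, seed=SEED), "vfa"):
    save_nifti(v, SCRATCH / f"vfa_fa{int(v.flags['flip_angle_deg']):02d}.nii")
print(f"vial_array  : 14 relaxometry vials (T1 {min(t1s):.0f}-{max(t1s):.0f} ms), "
      f"13 diffusion vials (ADC {min(adcs):.2e}-{max(adcs):.2e} mm^2/s)")

(RESULTS / "simulation_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
print(f"\nwrote {RESULTS / 'simulation_manifest.json'}")
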