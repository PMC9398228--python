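# mrlqa

Quality-assurance analysis for the MRI side of a 1.5 T MR-linac — the
hybrid machines that image with a diagnostic-grade scanner while a linear
accelerator delivers radiotherapy. Medical physicists monitor such systems
with daily phantom scans; this package implements the full analysis chain
behind that monitoring and exercises it end to end on synthetic phantom
images with known ground truth, so every estimator is testable without a
scanner.

It is written for physicists and imaging scientists who need:

* **daily image-quality metrics** — SNR (background-noise convention with
  Rayleigh correction), uniformity `(max−min)/(max+min) × 100%`, spatial
  linearity along eight compass directions, slice-profile FWHM and
  equivalent-width integral from an opposing wedge pair, pixel size from the
  line-spread function, and central-frequency deviation against
  `f₀ = γB₀` with `γ = 42.577478518 MHz/T`;
* **3D geometric distortion** — marker detection on a 7-plate, 1932-marker
  fiducial grid (25 mm in-plane / 55 mm between plates), rigid setup-error
  removal, and the maximum distortion per diameter of spherical volume
  (DSV 20/30/40/50 cm against 1/2/4/20 mm tolerances);
* **gantry-resolved field mapping** — B0 from dual-echo phase
  (`f = Δφ/2πΔTE`, in Hz and ppm), B1 from the dual-TR ratio inversion
  `α = arccos((rn−1)/(n−r))`, and peak-to-peak statistics per gantry angle
  with the across-angle mean map subtracted;
* **quantitative MRI** — variable-flip-angle T1 via the linearized spoiled
  steady-state equation `S/sin α = E₁·S/tan α + S₀(1−E₁)`, mono-exponential
  T2 (with dummy-echo discard) and ADC by log-linear least squares, per-vial
  bias `B = (measured−nominal)/nominal × 100%` and reproducibility
  `COV = σ/μ × 100%`, and the fractional-signal flip-angle optimizer;
* **longitudinal bookkeeping** — tolerance evaluation with
  printed-operator semantics, annualized drift fits, and CUSUM change-point
  flags.

## Layout

Library code lives in `src/mrlqa/` (`phantoms`, `piqt`, `distortion`,
`fieldmaps`, `qmri`, `report`); the numbered scripts under `analysis/` are
thin narrative drivers that run each stage on synthetic data and write
tables under `results/` (volumes go to `scratch/`). A thin `mrlqa` CLI
(`simulate`, `piqt`, `distortion`, `fieldmap`, `qmri`, `report`) wraps the
same library calls.

## Worked example

```bash
python analysis/03_distortion_3d.py
```

renders the 1932-marker phantom under a gradient-nonlinearity-like radial
field (`|v| = k·r³`, 3.1 mm at r = 250 mm) plus a 1.75 mm couch setup
shift, re-detects every marker, removes the setup error by rigid
alignment, and prints:

```
markers paired: 1932/1932 (setup shift |t| = 1.75 mm removed by alignment)
DSV (cm)  max |v| (mm)  tolerance  pass
   20          0.24       1.0     True
   30          0.70       2.0     True
   40          1.61       4.0     True
   50          3.11      20.0     True
```

The maxima grow monotonically away from isocenter and recover the imposed
field (3.1 mm at the DSV-50 boundary) to within the detector's ~0.1 mm
centroid accuracy; every DSV passes its tolerance. Likewise,

```bash
python analysis/04_field_homogeneity.py
```

simulates the 12-angle gantry sweep on the 40-cm cylinder and reports

```
worst raw B0 peak-to-peak: 2.99 ppm at gantry 180 deg
gantry-induced (mean-subtracted) peak-to-peak stays below 0.21 ppm — an order of magnitude smaller
B1 deviation from nominal: 1.20 +- 0.07 % across angles
worst-case displacement at 15 mT/m readout: 0.30 mm
```

i.e. the static shim residual dominates, rotation-locked perturbations are
an order of magnitude smaller, and even the worst inhomogeneity displaces
spins by only a third of a millimetre at the strongest readout gradient —
small against a 1 mm voxel.

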