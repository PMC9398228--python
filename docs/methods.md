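# Methods

This note records the models implemented in `mrlqa`, the choices made where
a vendor convention or protocol detail is not public, and what the
synthetic phantoms do and do not emulate.

## Coordinate and noise conventions

Machine coordinates are millimetres with the origin at the scanner
isocenter; arrays are indexed `voxels[ix, iy, iz]` and the world position
of a voxel center is `origin + index·spacing`. Volumes default to being
centered on the isocenter.

All generators share one noise model: independent zero-mean Gaussian noise
of standard deviation `noise_sd` is added per channel to the complex
signal, and the magnitude is taken. In-object voxels are therefore Rician
and pure-background voxels Rayleigh (mean/SD ≈ 1.913, the property the
suite uses to validate the model). Structures are rendered with
anti-aliased coverage (discs, rectangles, supersampled wedge ramps) or
smooth Gaussian blobs (fiducial markers), so centroids and edge positions
are defined to sub-voxel precision rather than quantized to the grid.

## Image-quality metrics

* **SNR** = mean(signal ROI) / noise, with noise = SD(background
  magnitude)/0.655 by default. The 0.655 factor (√(2−π/2)) converts the
  Rayleigh-compressed background SD back to the per-channel σ — the
  single-image background convention. A flag reports the raw-SD variant;
  the vendor's exact convention is not public, so both are exposed.
* **Uniformity** = (max−min)/(max+min) × 100% over the ROI after an
  optional Gaussian low-pass (FWHM given in mm, default one voxel in the
  drivers) that suppresses single-voxel extrema. The "large region of the
  phantom" is not specified anywhere authoritative; the ROI is caller-set.
* **Linearity**: hole centroids of the 45-hole, 25 mm grid are detected by
  thresholding the inverted body image, then refined by an iterated
  windowed centroid on the unthresholded inverse (removes
  threshold-truncation bias; identity grids read < 0.02%). Each of the
  eight compass directions is scored as the center-to-outermost-node
  distance on the exact ray vs its machined value. Radial (half-extent)
  distances give eight genuinely independent values; a full-diameter
  definition would duplicate N/S and E/W.
* **Slice profile**: the wedge maps through-plane position to the readout
  axis as `z = slope·x`; the band-averaged profile is converted to mm by
  the slope. FWHM uses linear interpolation between the bracketing
  samples (no spline — deterministic), and the integral is the equivalent
  width `sum(profile)/max · Δz`.
* **Pixel size** = FWHM of the line-spread function obtained by
  differentiating the edge-spread function along each axis. The reported
  quantity is the LSF FWHM in mm; whatever internal convention the vendor
  tool uses, the shipped tolerance (< 1.3/1.5 mm at 1.2 mm sampling)
  is applied to this quantity and the convention is stated here.
* **Central frequency**: deviation from `γ·B₀` in percent and ppm.

## 3D distortion

Markers are Otsu-thresholded, labelled, and their centroids refined on
unthresholded intensities with a robust (median + 3·MAD) soft threshold —
symmetric in the blob, zero without noise, so the refinement is exactly
unbiased in the noiseless limit and noise-robust otherwise (≤ 0.03 mm RMS
at object SNR 100). Pairing is nearest-known within half the grid
spacing; beyond that a marker counts as missing rather than silently
mismatched.

Setup error is removed by default with a rigid (Kabsch) least-squares
alignment of measured to known positions before vectors are formed; this
separates couch placement from machine distortion and can be disabled to
inspect raw vectors. Distortion magnitude is the Euclidean norm (the QA
tolerances are scalar), and the DSV summary takes the maximum over markers
with `|known| ≤ DSV/2`.

The in-plane plate layout is synthetic: the marker count and spacings are
fixed (1932 markers, 7 plates, 25/55 mm) but the plate outline is not
public, so the package uses a 25 mm grid inside a 231 mm-radius circle
minus the center point — exactly 276 markers per plate.

## Field mapping

B0: `f = wrap(φ₂−φ₁)/(2πΔTE)`, unambiguous within ±1/(2ΔTE) (±333.3 Hz at
the default ΔTE = 1.5 ms); generators flag truth fields beyond that range.
ppm = Hz/(γB₀ in MHz). No unwrapping is applied by default — QA fields sit
well inside the range — but a quality-guided spatial unwrapper is
available behind a flag for injected large offsets (correct up to a global
multiple of 1/ΔTE).

B1: the scanner-side reconstruction is proprietary, so simulation and
analysis adopt one self-consistent model — the interleaved dual-TR
(actual-flip-angle) pair, inverted with the long-T1 closed form
`cos α = (rn−1)/(n−r)`, `r = S(TR₂)/S(TR₁)`, `n = TR₂/TR₁`. The generator
defaults to the ideal long-T1 limit so the round trip is the identity
(< 0.01° over 10–85°); a finite-T1 steady state is available to study the
approximation error. Ratios outside `(1/n, 1)` are masked and counted.

Gantry sweeps subtract the voxelwise mean map across angles from each B0
map (removing the static shim contribution) and report the in-ROI range
("peak-to-peak", literal 0th/100th percentiles by default, 1st/99th behind
an option) per angle, both raw and mean-subtracted; for B1 the per-angle
mean |deviation from nominal| and its grand mean ± SD. The analysis ROI is
a 35-cm disc at the phantom center.

The displacement bound converts inhomogeneity to geometry as
`Δx = ΔB₀/G_read`: 3 ppm at 1.5 T (4.5 μT) over 15 mT/m is 0.30 mm.

## Quantitative MRI

T1 uses the linearized variable-flip-angle estimator — unweighted OLS of
`S/sin α` on `S/tan α` per voxel, `T1 = −TR/ln(slope)` — deliberately the
plain linear form as the default; a damped Gauss-Newton refinement on the
untransformed signal equation sits behind `method="nonlinear"` for cases
where the implicit noise weighting of the linearization matters (the two
agree to < 1e-6 relative on noiseless input). Slopes outside (0, 1),
flip-angle-independent signals, and fits with R² below 0.95 (configurable)
are masked, never zeroed. T2 and ADC are log-linear OLS on TE and b; any
non-positive sample masks the voxel. The MESE chain prepends a dummy echo
(flagged, +5% amplitude, emulating the stimulated-echo contamination of
the first echo) that `fit_t2_mese` discards by default; fitting it biases
T2 low by a few percent, which is what makes the discard rule testable.

The flip-angle designer returns the two roots of
`S(α) = f·S(θ_E)` (`θ_E = arccos e^(−TR/T1)`) by bracketed Brent root
finding, with `f = 0.71` as the standard fractional-signal criterion.
`design_vfa_pair` maps a T1 design range to one pair either at the range
midpoint (default — the midpoint of 1000–2000 ms reproduces the clinical
pair {4°, 22°} at TR = 20 ms) or by averaging the per-bound pairs
(which lands at {4°, 23°}); the criterion itself does not dictate the
choice, so both are exposed.

ROI statistics use a 1-cm-diameter circle per vial. Bias compares the
across-session mean with the nominal value; COV is SD/mean of the session
means with a **population** (n) denominator by default — this is the
convention under which three sessions at {100, 101, 99} give 0.816% — and
`cov_ddof=1` selects the sample convention. A single session reports COV
as undefined, not zero. Spearman rank tests of bias/COV against measured
value use exact permutation p-values for ≤ 8 vials and the large-sample
approximation beyond.

### Default vial sets and noise level

Relaxometry: 14 vials, T1 geometrically spaced over 500–2000 ms (the VFA
design range) and T2 over 40–200 ms — the range an 8-echo train at
TE = 22…99 ms can constrain (roughly up to twice the last echo); vials far
above that are conditioning-limited regardless of SNR, which no phantom
designer would pair with this protocol. Diffusion: 13 vials (center + two
rings of six), nominal ADC following the aqueous-PVP series at 0 °C,
1.1/0.82/0.59/0.40/0.25/0.13 × 10⁻³ mm²/s; ADC reporting uses the inner
ring by default.

Monte-Carlo checks run at **image SNR ≈ 100**, defined as the mean
in-vial signal of the acquired series over the per-channel noise σ
(`noise_sd_for_image_snr`). Anchoring noise to the equilibrium signal S₀
instead would put the two-point VFA images (which carry only ~8% of S₀)
at per-image SNR ≈ 8 — not a regime any phantom QA protocol operates in.

## Longitudinal bookkeeping

Tolerances follow the printed operator exactly: `>`/`<` strict, `>=`/`<=`
and closed intervals inclusive. Trends are OLS on days since the first
record (optionally normalized to percent of baseline) annualized by
365.25. Change-points use a tabular CUSUM (slack 0.5σ, threshold 4σ of
the first-30-session baseline) — a monitoring aid with the classic
false-alarm/latency trade-off (ARL₀ ≈ 170 samples at these settings), not
an inference procedure. Report JSON is canonical (sorted keys), so equal
inputs produce byte-identical files.

## What the synthetic data does not emulate

No eddy currents, susceptibility/EPI warping, chemical shift, coil
sensitivity profiles, temperature drift, or k-space simulation; phantom
positioning error appears only as the rigid shift the distortion pipeline
is designed to remove. Consequently, passing tests demonstrate estimator
correctness and noise behaviour under the stated models — they do not
certify performance against scanner-specific artifacts. One visible
consequence: week-to-week ADC variability in the real world is dominated
by setup/temperature/sequence effects, so the observed dependence of ADC
COV on vial value cannot be reproduced (or meaningfully tested) from
thermal noise alone; under the pure Rician model the relation is U-shaped
across the PVP range.

## Problem sizes

The suite renders full-size phantoms where geometry matters (the complete
1932-marker volume, 244×244×132 at 2×2×2.75 mm) and single-slice versions
elsewhere; Monte-Carlo envelopes use 50 realizations of the 160² (T1/T2)
and 128² (ADC) protocols, and daily-reproducibility properties 100
realizations — sizes chosen so the whole suite runs in well under a
minute per module on a laptop-class CPU.
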