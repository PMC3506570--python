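# cardiotract

Quantitative diffusion-tensor tractography of the heart.

Myocardial fibers wind around the left ventricle (LV) as helices whose
pitch — the **helix angle** (HA), the inclination of the fiber out of the
LV short-axis plane — varies smoothly across the wall: right-handed
(positive HA) in the subendocardium, circumferential at midwall,
left-handed (negative) in the subepicardium. Diffusion-tensor imaging
resolves the local fiber direction as the primary eigenvector ê₁ of the
per-voxel diffusion tensor; integrating ê₁ into streamlines turns a voxel
image into continuous 3D fiber tracts. `cardiotract` makes that
tractography *quantitative*: it classifies whole tracts by their HA
statistics, reduces a region of interest to transmural HA curves, and
summarizes architecture and data quality in a small set of scalar indices.
It is aimed at researchers studying myocardial microstructure — in
particular its reorganization in the remote zone of remodeled, infarcted
hearts — on ex-vivo DTI data or on the built-in synthetic phantoms.

## What it computes

**Tracking.** Streamlines are grown bidirectionally from seeds by
fourth-order Runge–Kutta integration of the sign-aligned, trilinearly
interpolated ê₁ field, with a step of ¼ voxel. A propagation angle above
35° between consecutive segments is the single geometric termination
criterion; tract length is optionally capped at half the LV circumference
(**πR**, with R the effective mid-wall radius) or clipped to the ROI.

**Whole-tract HA classification.** Each tract gets its discrete per-vertex
HA list plus four scalars: the minimum, maximum, median and mean HA along
the tract. The median is the workhorse statistic — robust to the HA
fluctuation that every long fiber shows near the apex and base.

**Transmural curves and the TCI.** Within an ROI, each tract deposits its
(min, med, max) into every voxel it traverses; averaging base→apex and
then anterior→posterior yields three transmural curves HA_min(x),
HA_med(x), HA_max(x) over normalized wall depth x ∈ [0, 1] (endo → epi).
The **tractographic coherence index** is

    TCI = ∫₀¹ HA_med(x)² dx
          ─────────────────────────────────────────────────────────
          ∫₀¹ (HA_max − HA_med)² dx + ∫₀¹ (HA_min − HA_med)² dx

High TCI means the tracts crossing each depth agree on their HA; values
below ≈ 0.1 at πR tract length indicate noisy data or disorganized fibers.

**Histogram and variance ratio.** The histogram of tract median HAs is
summarized by var(HA < 0) / var(HA > 0): ≈ 1 for a normal symmetric wall,
≪ 1 after the rightward (positive) HA shift seen in post-infarct
remodeling. The zero-crossing depth of HA_med(x) localizes the same shift.

**Histology orientation.** For 2D microscopy sections cut tangentially to
the epicardium, fiber orientation is recovered by Hessian ridge analysis:
ridge pixels (local extrema of the principal intensity curvature) are
thinned to single-pixel chains, and the section mean orientation is the
length-weighted axial circular mean of the segment angles.

**Phantom.** A synthetic LV segment — an annular cylinder with a linear
transmural HA profile, prescribed eigenvalues and per-voxel orientation
noise — provides ground truth for every stage, including forward-simulated
DWI and synthetic stripe images for the histology module. Presets:
`normal-human` (±60°), `normal-sheep` (±50°), `remote-zone` (+60/−37.5°).

## Worked example

```sh
cardiotract pipeline --preset normal-sheep --seed 1 --out-dir out/
```

runs the full synthetic study — phantom, πR-capped tracking, median-HA
classification, curves, TCI — and prints

```
INFO cardiotract: pipeline done: tci=11.901 variance_ratio=0.965 (5960 tracts)
```

`out/metrics.json` then contains

```json
{
  "n_tracts": 5960,
  "tci": 11.901448652761614,
  "variance_ratio": 0.9651352981119569,
  "zero_crossing": 0.5003114393607092,
  "effective_radius_mm": 29.250546096566044
}
```

Read: ~6,000 tracts were seeded in a transmural lateral-wall ROI; their
median-HA histogram is symmetric (variance ratio ≈ 0.97, i.e. the normal
balanced architecture), the median HA curve crosses zero at mid-wall
(0.50), and the TCI of 11.9 — far above the 0.1 coherence floor — says the
tracts at each depth agree tightly on their HA, as they should in a
noiseless-geometry phantom with only 5° orientation noise. Running
`--preset remote-zone` instead drives the variance ratio down (≈ 0.4) and
the zero-crossing toward the epicardium (≈ 0.62) at essentially unchanged
TCI: the remodeling signature is a *coherent* rightward rotation, not a
loss of organization.

The same stages are available piecewise (`phantom`, `fit`, `track`,
`classify`, `curves`, `tci`, `histogram`, `histo`) on NIfTI tensor/mask
volumes, FSL-style `bvals`/`bvecs`, VTK polyline tracts and PNG/TIFF
sections; see `cardiotract --help`.

## Layout

- `src/cardiotract/tensor_field.py` — tensor fit (log-linear LSQ), eigendecomposition
- `src/cardiotract/phantom.py` — synthetic LV, DWI simulation, stripe images
- `src/cardiotract/tractography.py` — RK4 tracking, termination, length policies, seeding
- `src/cardiotract/helix_angle.py` — LV frame, HA, whole-tract classification
- `src/cardiotract/quantify.py` — transmural curves, TCI, histograms, zero-crossing
- `src/cardiotract/histology.py` — Hessian ridge orientation of microscopy sections
- `src/cardiotract/io.py`, `cli.py`, `pipeline.py` — formats, CLI, end-to-end runs
- `docs/methods.md` — models, conventions, parameter choices, limitations

Tensor NIfTI files are 4D with six components per voxel in lower-triangular
order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz); files written by this tool carry a
header comment extension naming that order.
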