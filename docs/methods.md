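# Methods

## Model

The quantity estimated is the box-counting (Minkowski–Bouligand) fractal
dimension of the LV endocardial border on each short-axis slice. For a
bounded planar set, the number of grid cells of side `s` touching the set
scales as `N(s) ∝ s^{−FD}` over the scales at which the set is
self-similar; `FD` is estimated as minus the OLS slope of `ln N` against
`ln(s / image size)`. A smooth border has `FD → 1`; trabecular
irregularity that persists across scales raises it toward 2. The marker
is relative, not absolute: all readings carry the same finite-scale
biases (below), so diagnostic use rests on thresholds calibrated within
the same pipeline, never on comparing raw values across differently
configured analyses.

## Segmentation

- **Threshold.** Iterative intermeans on the ROI intensities:
  `t_{k+1} = (mean(I ≤ t_k) + mean(I > t_k))/2`, started at the ROI mean,
  stopped when the update falls below 0.5 intensity units (integer data)
  or 0.5 of a 256-bin quantization step (floating-point data), with a
  500-iteration cap. A constant ROI is an error ("degenerate
  histogram"), never a default. The variant is documented, not asserted
  to be bit-identical to any particular legacy implementation of the
  IsoData family.
- **Binarization.** Foreground = intensity strictly above threshold
  (bright blood pool, balanced-SSFP convention); pixels outside the ROI
  are background. A `bright_foreground=False` switch handles inverted
  contrast; edges are invariant under that inversion.
- **Edges.** 3×3 Sobel kernels on the {0,1} mask; border = gradient
  magnitude > 0. On binary input this is exactly the maximal-gradient
  locus and needs no magnitude cut-off. Across a step edge both adjacent
  pixels have nonzero gradient, so the border band is **two pixels
  wide**. No morphological cleanup is applied by default (an optional
  hole-filling flag exists): removing papillary/trabecular outlines
  silently would change the FD.

### Border-band bias

The 2-px band roughly doubles `N(s)` at the finest scales but not at the
coarsest, steepening the fit: a smooth circular border that measures
FD ≈ 1.06 as a 1-px raster measures ≈ 1.17 through the full pipeline at
a 55-px lumen radius. This is a property of the Sobel-band method
itself, shared by every reading it produces (smooth borders in the
target application read ≈ 1.16–1.23, not 1.0), and it cancels in
comparisons made within the pipeline. Calibration tests therefore pin
the 1-px analytic figures (circle 1.00–1.12; Koch ring ln 4/ln 3 ±
0.08; exact power law to machine precision), while pipeline-level tests
use the band-biased scale.

## Box counting

- Calibres are **consecutive integers** from 2 px to 45% of the border
  diameter (longer side of the border's tight bounding box; a maximal
  Feret diameter would differ only for oblique elongated borders and
  the bounding-box rule is deterministic and cheap). A ~126-px border
  yields 55 calibres.
- "Four orientations" = the four corners of the border bounding box used
  as grid anchors. Counting is exact (verified against a brute-force
  nested loop), not subsampled.
- The scale denominator ("image size" = longer side of the analyzed
  frame) shifts only the regression intercept; the FD is provably
  insensitive to it (asserted by test).
- The fit uses **all** calibres — no scaling-window selection. Two
  deterministic consequences, both documented rather than patched:
  counts of *consecutive-size* anchored grids are not strictly
  non-increasing (cells are not nested; size-doubling counts are, and
  the nesting inequality `N(2s) ≤ N(s)` is what the tests assert); and
  the count floor of ~3 boxes at the 45% cap biases near-1-D objects
  slightly downward (a straight line reads ≈ 0.93–0.94, not 1.0).
- Slice FD = arithmetic mean of the four per-orientation FDs (each
  orientation is fitted separately, then averaged — not count-averaged
  before one fit). A reading outside (0.9, 2.1) raises a quality flag
  on the result; nothing is clamped.

## Aggregation and perimetry

- Slices are analyzed base→apex; the most apical slice is excluded by
  default (partial-volume prone) and can be kept with a flag. Failed
  slices are excluded with a warning, never imputed.
- Thirds partition: contiguous, sizes differing by ≤ 1, remainder
  assigned basal-first then mid (10 → 4/3/3). By default thirds are
  computed over the analyzed slices; `thirds_over="acquired"` instead
  partitions all acquired positions, letting excluded slices keep their
  place.
- Perimeter: each 8-connected border component is hole-filled and its
  outer boundary traced by Moore-neighbour tracing (Jacob's stopping
  criterion); length = axial steps × pixel spacing + diagonal steps ×
  √2 × spacing, summed over components. The √2 chain estimator
  overestimates a digital circle by ≈ 5% — accepted as the documented
  convention rather than corrected, since the marker is used
  comparatively. Total perimeter is indexed to body-surface area.

## Comparator criteria

Petersen NC/C ratio (> 2.3 diagnostic, strict; maximal ratio across
views) and Jacquier trabeculated-mass fraction (> 20% diagnostic,
strict) are computed from operator-supplied measurements: wall
thicknesses, and per-slice contour areas converted to mass by disc
summation (area × (thickness + gap), gap inclusion configurable) at a
myocardial density of 1.05 g/ml (standard CMR convention; the source
methods leave it unstated). Contour semantics (papillary muscle in the
compacted mass; indistinguishable muscle treated as trabeculae) are
input conventions for the operator, not inferences made here.

## Statistics

- **AUC**: midrank (Mann–Whitney) estimator = `P(case > control) +
  ½P(tie)`; SE by the Hanley–McNeil approximation (`Q1 = A/(2−A)`,
  `Q2 = 2A²/(1+A)`).
- **Youden threshold**: exhaustive scan over midpoints between adjacent
  distinct scores plus sentinels; positive ⇔ score ≥ c; ties broken
  toward higher specificity (larger threshold).
- **Exact CIs**: Clopper–Pearson via Beta quantiles. At the boundary,
  `x = n` gives a lower bound solving `p^n = α/2` (30/30 → 88.4%,
  105/105 → 96.5%).
- **Bland–Altman**: bias ± 1.96 sd of paired differences;
  `RC = 1.96·√(ΣD_i²/(n−1))` with `n` = number of pairs; CoV = 100 ×
  sd(differences) / grand mean of all readings (the denominator is a
  package convention — the quantity has no single standard definition).
- **ICC**: two-way random effects, absolute agreement, single measures
  (ICC(2,1) ≡ McGraw–Wong ICC(A,1)), with the F-distribution CI;
  computed via `pingouin`. Chosen as the most defensible form for
  method comparison where readers are a random sample.
- **Fleiss κ** (point estimate via `statsmodels`) with a Wald CI from
  the Fleiss–Nee–Landis large-sample SE; the CI is deliberately not
  clipped to [−1, 1]. κ is undefined (error) when all ratings fall in
  one category.

## Phantoms

Phantoms emulate bright-blood short-axis contrast: background ≈ 35,
myocardial ring ≈ 60, blood pool ≈ 180 intensity units, additive
Gaussian noise sd 8 (SNR comfortably above threshold-failure levels, as
in routine bSSFP), 256-px frame at 1 mm spacing, 10 slices of 7 mm
thickness / 3 mm gap, basal lumen radius 55 px tapering to ~55% at the
apex. The lumen boundary is `r(θ) = r₀ + A·sin(nθ) + ρ(θ)` with `ρ` a
seeded spectral (1/f^β, β = 1.2) radial perturbation normalized to RMS
= A/2; optional dark papillary discs sit inside the mid-cavity pool.
Presets fix the study conditions: `normal` ramps the roughness
amplitude 1 → 2 px base→apex with 8 trabeculae; `lvnc` ramps 1.5 → 8 px
with 16, reproducing the apically-dominant pattern of
hypertrabeculation. Seeds are mandatory everywhere.

What phantoms do **not** model: true trabecular morphology (the
spectral perturbation is a controllable stand-in), partial-volume
averaging beyond pixelation, SSFP banding, coil shading, motion, or
through-plane effects. Passing the separation tests shows the pipeline
resolves boundary-roughness differences of the modelled kind at
realistic noise; it does not certify diagnostic accuracy on patients.

The Koch ring (classic 4-segment, scale-1/3 generator on each side of a
square; dimension ln 4/ln 3 independent of rasterization) is the
analytic calibration standard.

## Problem sizes

Deterministic checks (thresholding, counting oracles on ≤ 64×64 edges,
CI bounds, κ/ICC constructions at n ≤ 500) run in seconds. The
preset-separation experiment uses 20 synthetic subjects per arm at 6
slices each — enough for a stable AUC on a cleanly separated marker —
and the roughness grid uses 5 amplitude levels at one fixed seed, per
the generator's study conditions.

## Known limitations

- FD readings are pipeline-relative (band bias, all-points fit); they
  are comparable within this implementation, not across tools.
- The bounding-box border diameter is not rotation-invariant; a Feret
  option exists for oblique borders.
- The chain-code perimeter carries a ~5% convex-shape overestimate.
- DICOM reading covers plain single-frame series with standard spacing
  tags; enhanced multi-frame objects are out of scope.
- ROI rectangles are axis-aligned; free-form ROIs are not supported.
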