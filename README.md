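# cardiofract

Fractal-dimension quantification of left-ventricular (LV) trabeculation
from short-axis cine CMR stacks.

Excessive trabeculation — the hallmark of LV noncompaction (LVNC) — makes
the endocardial border complex and irregular. `cardiofract` measures that
complexity directly: each end-diastolic short-axis slice is segmented to a
binary endocardial-border image and its box-counting **fractal dimension
(FD)** is estimated. FD is a unitless index lying between 1 (a smooth
planar curve) and 2 (a space-filling one); a heavily trabeculated border
wrinkles at many scales and reads higher than a smooth one.

## Method

Per slice, inside a user-drawn rectangular ROI (the only manual step):

1. **Segmentation** — iterative-intermeans (IsoData) automatic threshold
   `t_{k+1} = (μ_{≤t} + μ_{>t})/2`; binarization with the bright blood
   pool as foreground; 3×3 Sobel edge detection (any nonzero gradient
   magnitude on the binary mask is a border pixel). Papillary and
   subvalvular structures captured by the threshold contribute their own
   outlines — they are part of the complexity being measured.
2. **Box counting** — grids of boxes with side `s = 2, 3, …, ⌊0.45·D⌋`
   px (`D` = border diameter) are laid over the edge image at four grid
   origins (the corners of the border bounding box); the number of boxes
   `N(s)` containing border pixels is counted. For each origin, ordinary
   least squares of `ln N` on `ln(s / image size)` gives `FD = −slope`;
   the slice FD is the mean of the four.
3. **Aggregation** — slice FDs (base→apex, most apical slice excluded by
   default) are averaged into a global LV FD, and the maximal FD is
   reported for the basal, mid and apical thirds. Summing each slice's
   traced border length gives total endocardial perimeter, indexed to
   body-surface area (mm/m²).

Alongside the fractal measure the package implements the two comparator
CMR criteria (Petersen NC/C wall-thickness ratio > 2.3; Jacquier
trabeculated mass > 20% of total LV mass), and the statistics used to
evaluate any such marker: Hanley ROC AUC, Youden-index thresholds,
sensitivity/specificity/predictive values with exact Clopper–Pearson 95%
CIs, Bland–Altman limits of agreement, repeatability coefficient
`RC = 1.96·√(ΣD_i²/(n−1))`, coefficient of variation, ICC(2,1) and
Fleiss' κ.

Because no patient scans ship with the package, a phantom module
generates synthetic bright-blood short-axis stacks with controllable
trabecular roughness (plus analytic calibration curves such as a Koch
ring of known dimension ln 4/ln 3 ≈ 1.262), so the whole pipeline is
testable end to end.

## Worked example

```bash
cardiofract phantom --preset lvnc --seed 17 --out demo
cardiofract analyze --stack demo/stack.tiff --bsa 1.9 --pixel-spacing 1.0 \
    --subject-id demo --out results
```

`results/demo_summary.json` (abridged):

```json
{
  "n_slices_analyzed": 9,
  "global_fd": 1.312,
  "max_fd_basal": 1.235,
  "max_fd_mid": 1.353,
  "max_fd_apical": 1.441,
  "total_perimeter_mm": 4229.23,
  "indexed_perimeter_mm_per_m2": 2225.91
}
```

The apically-weighted roughness of the `lvnc` preset shows as the
characteristic base→apex rise (max apical FD 1.441 ≫ basal 1.235);
`--preset normal` at the same seed stays near the smooth-border reading
(~1.17–1.25, see `docs/methods.md` on the border-band bias).
`results/demo_slices.csv` holds the per-slice FDs per grid orientation,
fit r² and traced perimeter. A `stats` subcommand computes ICC, Fleiss
κ, Bland–Altman or ROC summaries from a ratings CSV.

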