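# cardioseg

Fully automated single-cell segmentation and phenotype quantification for
dual-channel fluorescence micrographs of stem-cell-derived cardiomyocytes
(hiPSC-CMs): a nuclear stain (DAPI-like) plus a sarcomeric marker
(α-actinin-like) go in, per-cell morphology / texture / contact measurements
and dose-response statistics come out.

The hard part of this imaging regime is that α-actinin expression is wildly
heterogeneous — dim and bright cells share one field, edges between touching
cells are weak, and the intensity histogram is uni-modal and
background-dominated with a long bright tail.  A conventional global Otsu
threshold keeps only the bright cells.  This package instead masks cytoplasm
with **histogram-accelerated fuzzy C-means (EnFCM)**, minimizing

```
J = Σ_i Σ_l  h_l · u_il^m · (l − C_i)²ᅠᅠ(m > 1)
```

over the q gray levels l with pixel counts h_l, by alternating the
closed-form updates

```
u_il = ((C_i − l)²)^(−1/(m−1)) / Σ_j ((C_j − l)²)^(−1/(m−1))
C_i  = Σ_l h_l u_il^m l / Σ_l h_l u_il^m
```

The foreground/background cut-off is the lowest gray level whose foreground
membership reaches 0.5 (the center midpoint for C=2).  Clustering the
histogram instead of the pixels gives identical fixed points at a cost that
scales with q, not the megapixel count; the classical pixelwise FCM is kept
in the package as the brute-force oracle.

Individual cells are then delineated by:

1. **Nucleus seeds** — Otsu threshold of the nuclear channel, watershed on
   the negated Euclidean distance transform to split touching nuclei, and a
   closing-based merge so the two nuclei of a bi-nucleate cardiomyocyte act
   as one seed.
2. **Seed propagation** — multi-source lowest-cumulative-cost region growing
   through the cell mask, with step cost `sqrt(ΔI² + λ·step²)` on
   contrast-normalized intensity; λ = 1 weighs intensity differences and
   spatial distance equally.
3. **Phenotyping** — per cell: area, perimeter, mean intensity; best-fit
   ellipse axes, elongation 1−short/long, compactness 4πA/P², extension,
   dispersion; five first-order texture statistics (std, smoothness,
   skewness, uniformity, entropy) on both channels; cell-cell contact
   fraction and nuclear-intensity CV.  Treated conditions are compared with
   the vehicle control feature-by-feature with two-sample
   Kolmogorov–Smirnov tests (p < 0.05).

A synthetic-scene generator with exact ground truth (spread ≈500 cells/mm²
and clustered ≈2000 cells/mm² regimes, bi-nucleation, dim-cell majority,
sarcomere-like striation, Poisson+Gaussian noise) makes every stage testable
without any external data, including planted dose effects (cell loss,
shrinkage, rounding, chromatin condensation).

## Worked example

```bash
python examples/segment_scene.py
```

```
planted cells : 13
detected seeds: 13
segmented     : 13
pixel precision 0.972  recall 0.936  F 0.954
```

Thirteen planted cells give thirteen seeds and thirteen segmented cells; the
pixel F-score of 0.95 against the planted masks means outlines are recovered
almost exactly (residual disagreement sits at smoothing-blurred cell rims).
The companion example `fuzzy_vs_otsu_masking.py` shows why the fuzzy cut-off
matters:

```
fuzzy cut-off :   50.3 gray levels
Otsu threshold:  127.0 gray levels
dim-cell pixel recall   fuzzy 0.922   Otsu 0.006
bright-cell pixel recall fuzzy 1.000   Otsu 0.992
```

Otsu's threshold lands above the dim-cell band and erases those cells; the
membership cut-off keeps 92 % of their pixels.  `phenotype_features.py` and
`dose_response.py` demonstrate the measurement panel and the KS-based
cytotoxicity read-out (cell number as % of control, planted area shrinkage
flagged significant).

There is also a thin CLI over the same library code:

```bash
cardioseg simulate --n-images 2 --out scenes
cardioseg segment --nuclear scenes/scene000_nuc.tif --cytoplasm scenes/scene000_cyto.tif --out seg
cardioseg features --seeds seg/scene000_cyto_seeds.tif --cells seg/scene000_cyto_cells.tif \
    --nuclear scenes/scene000_nuc.tif --cytoplasm scenes/scene000_cyto.tif --out cells.csv
cardioseg evaluate --pred seg/scene000_cyto_cells.tif --ref scenes/scene000_gt_cells.tif
cardioseg report --table cells.csv --control control
```

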