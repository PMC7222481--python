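# Methods

## Pipeline model

The pipeline treats a field of view as a pair of co-registered 2D rasters:
a nuclear stain and a cytoplasmic sarcomeric marker.  Segmentation assumes
(i) every cell contains at least one detectable nucleus, (ii) nuclei are
compact blobs separable by the distance transform even when touching, and
(iii) cytoplasmic signal, however heterogeneous, is brighter than the
residual background after background subtraction.  Cells without nuclei
(debris, anucleate fragments) are deliberately left unlabeled.

Stages and their defaults:

| stage | operation | defaults | units / notes |
|---|---|---|---|
| preprocess | rolling-ball background subtraction | radius 100 (cytoplasm), 50 (nuclear) | px; ImageJ-style shrink acceleration above radius 32 |
| | Gaussian smoothing | σ 5 (cytoplasm), 2 (nuclear) | "radius" read as the Gaussian σ, the ImageJ convention |
| | median filter (cytoplasm only) | radius 5 | disc neighborhood |
| | linear contrast enhancement (cytoplasm only) | 0.3 % saturated pixels | quantile stretch, no equalization |
| nuclei | Otsu threshold → area filter → distance watershed → closing merge | min_area 50 px², merge_radius 1 px, seed_min_distance 5 px | 8-connectivity |
| cell mask | EnFCM over the gray-level histogram | q 256, C 2, m 2, tol 1e-4, max_iter 300 | cut-off at foreground membership 0.5 |
| propagate | lowest-cost multi-source growing | λ 1.0, 8-connectivity | step cost sqrt(ΔI² + λ·step²) |
| statistics | two-sample KS vs control | α 0.05, no multiplicity correction | Benjamini–Hochberg available, off by default |

### EnFCM details

For integer-valued images whose observed range fits in q levels the
histogram uses the raw gray values as levels (h_l is literally the count of
pixels at gray value l), which makes the histogram fit *exactly* equivalent
to pixelwise FCM — verified in the tests to 1e-6 on centers and objective.
Cluster centers are initialized deterministically at the 25th/75th
intensity-weighted percentiles.  The alternating updates converge to a
local minimum of J; on background-dominated histograms with a dim-cell mode
and a sparse bright tail two fixed points exist (a dim-inclusive one and a
bright-only one), and the percentile initialization lands in the
dim-inclusive basin, which is the behavior the screening application needs.
No restart/min-J selection is performed: the bright-only fixed point can
have the lower J while being the wrong masking for dim cells, so objective
value is not a valid selection criterion here.  A level coinciding exactly
with a center takes membership 1 in that cluster.  Coincident centers raise
an error rather than guessing a cut-off.

### Nucleus seeding

The distance watershed is seeded at local maxima of the EDT smoothed with a
1-px Gaussian, with maxima closer than `seed_min_distance` (5 px)
suppressed and connected equal-valued plateaus collapsed to one marker.
Plain h-maxima suppression (h = 1 distance unit) was evaluated first and
rejected: on realistic noisy masks it emits spurious single-pixel maxima
along gently curved EDT ridges and fragments single nuclei, and no h value
separates bi-nucleate dumbbell saddles from genuinely touching nuclei.
Watershed ridge pixels are assigned to the nearest basin so labels tile the
mask exactly.  The closing-based merge fuses only components that were
separate before the closing and connected after it; watershed-split labels
(already touching) are never re-fused, otherwise every split would be
undone.

### Propagation

Intensities are rescaled to [0,1] over the image's range before the cost
evaluation so λ = 1 genuinely balances the intensity and distance terms.
Path costs are quantized at 1e-12 and ties go to the lowest seed id, making
the labeling deterministic; agreement with an independent sparse-graph
Dijkstra implementation is exact away from cost ties.  As λ → ∞ the
partition converges to the geodesic Voronoi diagram of the mask; as λ → 0
boundaries lock onto intensity edges.

### Features

Perimeter defaults to the Crofton 4-direction estimator so a rasterized
disc attains compactness ≈ 1 (the naive 4-connected boundary count, under
which a 10×10 square measures 36, is available as `perimeter_mode="naive"`).
Compactness is 4πA/P² — the π belongs in the formula even though informal
write-ups often drop it, since the circle must score 1.  Extension is log2
of the best-fit-ellipse axis ratio; dispersion is log2 of the ratio of the
mean radial distance to that of the equal-area disc (2R/3).  Texture uses
the region's min-max-normalized intensities binned into 256 levels
(`bins=None` keeps every distinct value and reproduces per-pixel moments to
1e-9); both channels are measured, with `cyto_`/`nuc_` prefixes, since
either can carry condition-dependent texture.  Contact counts boundary
pixels (8-neighborhood, image border counts as outside) adjacent to a
different nonzero label.  Nuclear CV is computed over the cell's seed
region on the nuclear channel.

### Statistics

The KS statistic is the exact sup-distance between the two empirical CDFs.
P-values are exact (conditional enumeration) when both samples hold ≤ 25
observations and otherwise use the classic asymptotic Kolmogorov series at
λ = √(nm/(n+m))·D.  Significance is p < 0.05 per feature with no
multiple-testing correction, matching common screening practice; a
Benjamini–Hochberg option exists for users who prefer FDR control.
Segmentation quality aggregates per-image precision/recall/F as mean ± SEM
across images (a pooled-pixel mode is available); note mean-of-F is not
F-of-means, and both are reported deliberately distinct.

## Synthetic scenes: what they emulate and what they do not

Scenes emulate the documented difficulties of this imaging regime: a
background-dominated, uni-modal, long-tailed cytoplasmic histogram; strong
inter-cell expression differences with dim cells at 30 % of bright-cell
amplitude; sarcomere-like sinusoidal striation (period 6 px ≈ 2 µm at the
assumed 0.32 µm/px); weak edges between touching cells; bi-nucleation
(25 % of cells, rendered as overlapping dumbbell blobs with additive
chromatin signal); spread (≈500 cells/mm²) and clustered (≈2000 cells/mm²)
growth with realistic 500–900 µm² spread-cell footprints; smooth background
fluorescence plus Poisson shot noise and Gaussian read noise.

Two generator choices are calibrated by construction and deserve emphasis:

* **Dim-cell majority, enforced on pixel mass.**  The ordering the masking
  stage must reproduce — fuzzy cut-off below the dim band, Otsu above it —
  exists only when dim cells dominate the foreground mass and bright cells
  form a sparse tail (bright fraction ≈ 0.18 of foreground pixels at ≈ 33 %
  coverage).  The generator therefore assigns bright expression to a
  subset of cells chosen by a small subset-sum search so the bright pixel
  mass hits the configured fraction exactly; a per-cell coin flip would
  make the histogram regime a per-scene lottery at ~13 cells per field.
  This is a statement about the imaging regime being emulated, not a claim
  that every culture looks like this: on fields where bright cells carry
  much more of the mass, the fuzzy threshold converges to the bright-only
  fixed point and behaves like Otsu.

* **Ground-truth boundaries.**  Overlapping cells are resolved by claim
  order during packing, limited so every cell keeps ≥ 70 % (spread) or
  ≥ 60 % (clustered) of its own pixels; heavier overlap would plant
  boundaries no segmenter could infer from the image.

Scenes do not model optics (no PSF), montage stitching seams, uneven
illumination beyond a smooth additive field, mitotic figures, or
multinucleation beyond two nuclei.  Passing tests therefore demonstrate
correct algorithmic behavior under the stated regime, not performance on
any particular microscope's data.

## Validation problem sizes

Default scenes are 512×512 px (13 cells spread / 54 clustered at
0.32 µm/px).  End-to-end recovery is validated on ten spread scenes
(pixel F ≥ 0.85 required; observed ≈ 0.95) plus three scenes per density
regime for per-cell IoU recovery (≥ 90 % of cells at IoU ≥ 0.6).  The
dose-response check runs the full pipeline on a six-condition series
(control + five doses, planted cell loss 0→0.75 and shrinkage 0→0.5, five
replicates) at 256×256; the null false-positive calibration measures the
full feature panel on ground-truth labels over twelve independent
group-pairs (no segmentation, so several hundred KS draws stay cheap).
The EnFCM–FCM equivalence uses twenty random 64×64 images; the propagation
oracle uses 48×48 two-seed fixtures at λ ∈ {0.01, 1, 100}.

## Known limitations

* The propagation cost's exact functional form is the package's own
  (sqrt-combined, normalized ΔI); it honors the equal-impact contract at
  λ = 1 and is pinned by the Dijkstra oracle, but other cost conventions
  exist in the literature.
* Cells whose nuclei fail to image (or anucleate fragments) are not
  recovered, by design.
* The fuzzy cut-off is a global per-image threshold; spatially adaptive
  variants (FCM_S-family) are out of scope.
* Texture features are first-order (histogram) statistics only — no
  co-occurrence or striation-periodicity analysis.
* The pure-Python Dijkstra propagation is the slowest stage (~1 s per
  512×512 field); montage-scale inputs stream image-by-image.
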