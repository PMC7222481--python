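"""Single-cell phenotype measurements: basic, shape, texture and contact features.

Four categories of per-cell read-outs quantify the cardiotoxicity phenotype:

* basic — area (px²), perimeter (px), mean raw intensity;
* shape — best-fit-ellipse axes, elongation (1 − short/long), compactness
  4πA/P² (1 for a circle), plus the log2 moment descriptors extension and
  dispersion;
* texture — std, smoothness, skewness, uniformity and entropy of the
  region's normalized intensity histogram, computed per channel;
* contact — fraction of a cell's boundary shared with other cells, and the
  coefficient of variation of nuclear intensity over the cell's seed (a
  chromatin-condensation proxy).

Perimeter defaults to the Crofton multi-directional estimator so that a
rasterized circle attains compactness ≈ 1; the naive 4-connected boundary
count is available as ``perimeter_mode="naive"``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import perimeter as perimeter_naive
from skimage.measure import perimeter_crofton, regionprops

from .io_core import CellRecord, ChannelPair, Image, LabelMask

__all__ = [
    "RegionHistogram",
    "ShapeFeatures",
    "TextureFeatures",
    "ContactFeatures",
    "FEATURE_REGISTRY",
    "region_histogram",
    "basic_features",
    "shape_features",
    "texture_features",
    "contact_features",
    "measure_image",
]

#: Ordered feature-column registry; CSV schemas follow this order.
FEATURE_REGISTRY: tuple[str, ...] = (
    "area",
    "perimeter",
    "mean_intensity",
    "long_axis",
    "short_axis",
    "elongation",
    "compactness",
    "extension",
    "dispersion",
    "cyto_std",
    "cyto_smoothness",
    "cyto_skewness",
    "cyto_uniformity",
    "cyto_entropy",
    "nuc_std",
    "nuc_smoothness",
    "nuc_skewness",
    "nuc_uniformity",
    "nuc_entropy",
    "contact_fraction",
    "nuclear_cv",
)


@dataclasses.dataclass
class RegionHistogram:
    """Normalized intensity histogram of one region on the [0,1] scale."""

    H: np.ndarray          # probabilities, sum to 1
    values: np.ndarray     # intensity value of each bin (the index i)

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.H.shape != self.values.shape:
            raise ValueError("H and values must align")
        if (self.H < -1e-12).any() or abs(float(self.H.sum()) - 1.0) > 1e-9:
            raise ValueError("RegionHistogram must be a normalized histogram")

    @property
    def mean(self) -> float:
        return float((self.H * self.values).sum())


@dataclasses.dataclass
class ShapeFeatures:
    area: float
    perimeter: float
    extension: float
    dispersion: float
    elongation: float
    compactness: float
    long_axis: float
    short_axis: float


@dataclasses.dataclass
class TextureFeatures:
    std: float
    smoothness: float
    skewness: float
    uniformity: float
    entropy: float


@dataclasses.dataclass
class ContactFeatures:
    contact_fraction: float
    nuclear_cv: float


def _region_mask(labels: LabelMask, cell_id: int) -> np.ndarray:
    if cell_id <= 0 or cell_id > labels.n_objects:
        raise KeyError(f"cell id {cell_id} not present in label mask")
    region = labels.pixels == cell_id
    if not region.any():
        raise KeyError(f"cell id {cell_id} has no pixels")
    return region


def region_histogram(img: Image, region: np.ndarray,
                     bins: int | None = 256) -> RegionHistogram:
    """Normalized histogram of a region's intensities mapped to [0,1].

    Intensities are min-max normalized over the region before binning, so
    texture features are comparable across cells of different brightness.
    ``bins=None`` keeps every distinct intensity as its own level (full
    resolution, exact moments).  A constant region yields all mass in the
    single bin at 0.
    """
    vals = img.astype_float()[region]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return RegionHistogram(H=np.array([1.0]), values=np.array([0.0]))
    norm = (vals - lo) / (hi - lo)
    if bins is None:
        uniq, counts = np.unique(norm, return_counts=True)
        return RegionHistogram(H=counts / counts.sum(), values=uniq)
    counts, edges = np.histogram(norm, bins=bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RegionHistogram(H=counts / counts.sum(), values=centers)


def basic_features(
    labels: LabelMask, img: Image, cell_id: int, perimeter_mode: str = "crofton"
) -> dict[str, float]:
    """Area (px²), perimeter (px) and mean raw intensity of one cell."""
    region = _region_mask(labels, cell_id)
    area = float(region.sum())
    if perimeter_mode == "crofton":
        perim = float(perimeter_crofton(region, directions=4))
    elif perimeter_mode == "naive":
        perim = float(perimeter_naive(region, neighborhood=4))
    else:
        raise ValueError(f"unknown perimeter_mode {perimeter_mode!r}")
    mean_int = float(img.astype_float()[region].mean())
    return {"area": area, "perimeter": perim, "mean_intensity": mean_int}


def shape_features(
    labels: LabelMask, cell_id: int, perimeter_mode: str = "crofton"
) -> ShapeFeatures:
    """Moment-based shape descriptors of one cell.

    Axes come from the best-fit ellipse via second-order central moments;
    elongation = 1 − short/long; compactness = 4πA/P²; extension = log2 of
    the axis ratio; dispersion = log2 of the ratio of the mean radial
    distance to the equivalent-disc radius.  Degenerate (collinear) regions
    floor the short axis at 1 px.
    """
    region = _region_mask(labels, cell_id)
    area = float(region.sum())
    if area < 5:
        raise ValueError(f"cell {cell_id}: shape features need area >= 5 px, got {area:g}")
    props = regionprops(region.astype(np.uint8))[0]
    long_axis = float(props.axis_major_length)
    short_axis = max(float(props.axis_minor_length), 1.0)
    long_axis = max(long_axis, short_axis)
    if perimeter_mode == "crofton":
        perim = float(perimeter_crofton(region, directions=4))
    else:
        perim = float(perimeter_naive(region, neighborhood=4))
    elongation = 1.0 - short_axis / long_axis
    compactness = 4.0 * math.pi * area / (perim ** 2) if perim > 0 else 0.0
    rr, cc = np.nonzero(region)
    cy, cx = rr.mean(), cc.mean()
    mean_radial = float(np.hypot(rr - cy, cc - cx).mean())
    # equivalent disc of the same area; its mean radial distance is 2R/3
    eq_radius = math.sqrt(area / math.pi)
    dispersion = math.log2(mean_radial / ((2.0 / 3.0) * eq_radius)) if mean_radial > 0 else 0.0
    extension = math.log2(long_axis / short_axis)
    return ShapeFeatures(
        area=area, perimeter=perim, extension=extension, dispersion=dispersion,
        elongation=elongation, compactness=compactness,
        long_axis=long_axis, short_axis=short_axis,
    )


def texture_features(hist: RegionHistogram) -> TextureFeatures:
    """The five first-order texture statistics of a region histogram.

    f1 (std)        sqrt(Σ (i − mean)² H(i))
    f2 (smoothness) 1 − 1/(1 + f1²)      — 0 for constant intensity
    f3 (skewness)   Σ (i − mean)³ H(i)   — 0 for symmetric histograms
    f4 (uniformity) Σ H(i)²              — 1 when all mass sits at one level
    f5 (entropy)    −Σ H(i) log2 H(i)    with 0·log 0 := 0
    """
    H, i = hist.H, hist.values
    mean = hist.mean
    f1 = math.sqrt(float(((i - mean) ** 2 * H).sum()))
    f2 = 1.0 - 1.0 / (1.0 + f1 ** 2)
    f3 = float(((i - mean) ** 3 * H).sum())
    f4 = float((H ** 2).sum())
    pos = H[H > 0]
    f5 = float(-(pos * np.log2(pos)).sum())
    return TextureFeatures(std=f1, smoothness=f2, skewness=f3, uniformity=f4, entropy=f5)


def _boundary_pixels(region: np.ndarray) -> np.ndarray:
    """Region pixels with >= 1 non-region pixel in their 8-neighborhood.

    The raster border counts as outside, so cells touching the image edge
    have boundary there too.
    """
    padded = np.pad(region, 1, mode="constant", constant_values=False)
    interior = ndi.binary_erosion(padded, structure=np.ones((3, 3)))[1:-1, 1:-1]
    return region & ~interior


def contact_features(
    labels: LabelMask, nuclear_img: Image, seeds: LabelMask, cell_id: int
) -> ContactFeatures:
    """Cell-cell contact fraction and nuclear-intensity coefficient of variation.

    Contact: share of the cell's boundary pixels whose 8-neighborhood holds
    a different nonzero label — a proxy for monolayer integrity.  Nuclear
    CV: std/mean of the nuclear channel over the cell's seed region;
    elevated values indicate chromatin condensation.
    """
    region = _region_mask(labels, cell_id)
    boundary = _boundary_pixels(region)
    total = int(boundary.sum())
    if total == 0:
        contact = 0.0
    else:
        others = (labels.pixels > 0) & ~region
        near_other = ndi.binary_dilation(others, structure=np.ones((3, 3)))
        contact = float((boundary & near_other).sum()) / total
    seed_region = seeds.pixels == cell_id
    if not seed_region.any():
        raise RuntimeError(f"cell {cell_id} has no seed region; masks are inconsistent")
    vals = nuclear_img.astype_float()[seed_region]
    mean = float(vals.mean())
    cv = float(vals.std()) / mean if mean > 0 else 0.0
    return ContactFeatures(contact_fraction=contact, nuclear_cv=cv)


def measure_image(
    labels: LabelMask,
    pair: ChannelPair,
    seeds: LabelMask,
    image_id: str = "image",
    condition: str = "control",
    texture_bins: int = 256,
) -> tuple[list[CellRecord], dict[str, float]]:
    """One CellRecord per cell plus the per-image summary (cell_number).

    Texture features are computed on both channels and emitted with
    ``cyto_``/``nuc_`` prefixes.  The total cell count of the image is the
    viability read-out of the screen.
    """
    if labels.shape != pair.shape or seeds.shape != pair.shape:
        raise ValueError("labels, seeds and channels must share a shape")
    records: list[CellRecord] = []
    for cell_id in range(1, labels.n_objects + 1):
        region = labels.pixels == cell_id
        basic = basic_features(labels, pair.cytoplasm, cell_id)
        shape = shape_features(labels, cell_id) if region.sum() >= 5 else None
        cyto_tex = texture_features(region_histogram(pair.cytoplasm, region, texture_bins))
        nuc_tex = texture_features(region_histogram(pair.nuclear, region, texture_bins))
        contact = contact_features(labels, pair.nuclear, seeds, cell_id)
        feats: dict[str, float] = dict(basic)
        if shape is not None:
            feats.update(
                long_axis=shape.long_axis, short_axis=shape.short_axis,
                elongation=shape.elongation, compactness=shape.compactness,
                extension=shape.extension, dispersion=shape.dispersion,
            )
        else:
            feats.update(long_axis=np.nan, short_axis=np.nan, elongation=np.nan,
                         compactness=np.nan, extension=np.nan, dispersion=np.nan)
        for prefix, tex in (("cyto", cyto_tex), ("nuc", nuc_tex)):
            feats.update({
                f"{prefix}_std": tex.std,
                f"{prefix}_smoothness": tex.smoothness,
                f"{prefix}_skewness": tex.skewness,
                f"{prefix}_uniformity": tex.uniformity,
                f"{prefix}_entropy": tex.entropy,
            })
        feats["contact_fraction"] = contact.contact_fraction
        feats["nuclear_cv"] = contact.nuclear_cv
        records.append(CellRecord(cell_id=cell_id, image_id=image_id,
                                  condition=condition, features=feats))
    summary = {"cell_number": float(labels.n_objects)}
    return records, summary
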