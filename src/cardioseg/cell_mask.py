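"""Cytoplasm foreground masking by histogram-accelerated fuzzy C-means (EnFCM).

The α-actinin channel of a cardiomyocyte montage has a uni-modal,
background-dominated intensity histogram with a long high-intensity tail:
strong and weak cells coexist in one image, so a single hard threshold such
as Otsu's tends to keep only the strong signal.  Fuzzy C-means assigns each
gray level a soft degree of belonging to foreground, and the cut-off at the
level where foreground membership reaches 0.5 retains weak cells.

EnFCM runs the fuzzy clustering over the q-level gray histogram rather than
over individual pixels.  The objective

    J = Σ_i Σ_l  h_l · u_il^m · (l − C_i)²,     m > 1,

with h_l the pixel count at gray level l, has the same fixed points as
pixelwise FCM on the expanded pixel list, at a cost that scales with q
instead of the pixel count.  Alternating the closed-form updates

    u_il = ((C_i − l)²)^(−1/(m−1)) / Σ_j ((C_j − l)²)^(−1/(m−1))
    C_i  = Σ_l h_l u_il^m l / Σ_l h_l u_il^m

monotonically decreases J.  The pixelwise variant is retained as the
brute-force correctness oracle.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.filters import threshold_otsu

from .io_core import BinaryMask, Image

__all__ = [
    "IntensityHistogram",
    "FuzzyClusterModel",
    "EnFCMParams",
    "image_histogram",
    "enfcm_fit",
    "fcm_fit_pixelwise",
    "membership_threshold",
    "mask_cells",
    "mask_cells_otsu",
]


class DegenerateHistogramError(ValueError):
    """The image has too few distinct gray values to cluster or threshold."""


@dataclasses.dataclass
class IntensityHistogram:
    """Gray-level counts over ``q`` levels spanning the observed range.

    ``level_values`` maps each level index to the raw intensity at the bin
    center, so cluster centers and thresholds come out in intensity units.
    """

    q: int
    h: np.ndarray
    level_values: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.level_values = np.asarray(self.level_values, dtype=np.float64)
        if self.h.shape != (self.q,) or self.level_values.shape != (self.q,):
            raise ValueError("histogram arrays must have length q")
        if (self.h < 0).any():
            raise ValueError("histogram counts must be non-negative")

    @property
    def n_pixels(self) -> int:
        return int(round(float(self.h.sum())))


@dataclasses.dataclass
class FuzzyClusterModel:
    """Fitted fuzzy clustering: centers, per-level memberships and diagnostics."""

    C: int
    m: float
    centers: np.ndarray          # ascending, gray-value units
    memberships: np.ndarray      # C × q, rows follow `centers`
    levels: np.ndarray           # gray values the membership columns refer to
    J: float
    iterations: int
    converged: bool
    j_history: np.ndarray | None = None   # objective after each iteration

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.memberships = np.asarray(self.memberships, dtype=np.float64)
        self.levels = np.asarray(self.levels, dtype=np.float64)
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.J < 0:
            raise ValueError("objective J must be non-negative")


@dataclasses.dataclass
class EnFCMParams:
    """Parameters of the EnFCM masking stage."""

    q: int = 256
    C: int = 2
    m: float = 2.0
    tol: float = 1e-4
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 2 or self.C < 2 or self.m <= 1:
            raise ValueError("require q >= 2, C >= 2, m > 1")


def image_histogram(img: Image, q: int = 256) -> IntensityHistogram:
    """Gray-level histogram with ``q`` levels over the observed [min, max].

    For integer-valued images whose observed range fits within ``q`` levels
    the levels are the raw gray values themselves (h_l = count of pixels at
    gray value l); otherwise intensities are binned linearly into ``q``
    levels.  Binning the observed range (not the nominal bit range) keeps
    full resolution for 16-bit images with low dynamic range.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    pixels = img.astype_float().ravel()
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        raise DegenerateHistogramError("constant image has a degenerate histogram")
    integral = bool(np.all(pixels == np.round(pixels)))
    span = int(hi - lo) + 1 if integral else None
    if integral and span is not None and span <= q:
        levels = lo + np.arange(span, dtype=np.float64)
        counts = np.bincount((pixels - lo).astype(np.int64), minlength=span)
        return IntensityHistogram(q=span, h=counts.astype(np.float64), level_values=levels)
    counts, edges = np.histogram(pixels, bins=q, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return IntensityHistogram(q=q, h=counts.astype(np.float64), level_values=centers)


def _fcm_alternate(
    values: np.ndarray,
    weights: np.ndarray,
    C: int,
    m: float,
    tol: float,
    max_iter: int,
    init_centers: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, np.ndarray]:
    """Weighted FCM over 1D values: the shared engine of EnFCM and pixelwise FCM.

    Pixelwise FCM is the special case of unit weights on the raw pixel list;
    EnFCM passes histogram counts.  Returns (centers, memberships, J, iters,
    converged, j_history) with centers sorted ascending; j_history holds the
    objective after each membership+center update, a non-increasing sequence
    by the alternating-minimization argument.
    """
    centers = np.sort(np.asarray(init_centers, dtype=np.float64))
    expo = -1.0 / (m - 1.0)
    u = np.empty((C, values.size))
    converged = False
    it = 0
    j_history: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = (centers[:, None] - values[None, :]) ** 2      # C × L
        exact = d2 < 1e-300
        if exact.any():
            # a level sitting on a center belongs to that cluster outright
            u = np.zeros_like(d2)
            col_hit = exact.any(axis=0)
            first = np.argmax(exact, axis=0)
            u[first[col_hit], np.flatnonzero(col_hit)] = 1.0
            free = ~col_hit
            if free.any():
                w = d2[:, free] ** expo
                u[:, free] = w / w.sum(axis=0, keepdims=True)
        else:
            w = d2 ** expo
            u = w / w.sum(axis=0, keepdims=True)
        um = u ** m
        num = (weights[None, :] * um * values[None, :]).sum(axis=1)
        den = (weights[None, :] * um).sum(axis=1)
        new_centers = np.where(den > 0, num / np.maximum(den, 1e-300), centers)
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = np.sort(new_centers)
        j_history.append(float(
            (weights[None, :] * um * (centers[:, None] - values[None, :]) ** 2).sum()
        ))
        if shift < tol:
            converged = True
            break
    d2 = (centers[:, None] - values[None, :]) ** 2
    J = float((weights[None, :] * (u ** m) * d2).sum())
    return centers, u, J, it, converged, np.asarray(j_history)


def _percentile_init(values: np.ndarray, weights: np.ndarray, C: int) -> np.ndarray:
    """Deterministic init: centers at evenly spaced weighted quantiles (25/75 for C=2)."""
    qs = (np.arange(C) + 1) / (C + 1)  # C=2 -> 1/3, 2/3 ... use 25/75 for C=2
    if C == 2:
        qs = np.array([0.25, 0.75])
    order = np.argsort(values)
    cw = np.cumsum(weights[order])
    cw = cw / cw[-1]
    idx = np.searchsorted(cw, qs, side="left")
    init = values[order][np.clip(idx, 0, values.size - 1)]
    # guard against coincident starts on spiky histograms
    if np.unique(init).size < C:
        init = np.linspace(float(values.min()), float(values.max()), C + 2)[1:-1]
    return init


def enfcm_fit(
    hist: IntensityHistogram,
    C: int = 2,
    m: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyClusterModel:
    """Fit fuzzy clusters to the gray-level histogram (EnFCM).

    ``seed`` is accepted for interface symmetry with optional random
    restarts; the default initialization (25th/75th weighted percentiles) is
    deterministic.
    """
    if C < 2 or m <= 1:
        raise ValueError("require C >= 2 and m > 1")
    populated = hist.h > 0
    if int(populated.sum()) < C:
        raise ValueError(
            f"cannot fit {C} clusters to {int(populated.sum())} populated gray levels"
        )
    values = hist.level_values[populated]
    weights = hist.h[populated]
    init = _percentile_init(values, weights, C)
    centers, u_pop, J, iters, converged, j_hist = _fcm_alternate(
        values, weights, C, m, tol, max_iter, init
    )
    u = np.zeros((C, hist.q))
    u[:, populated] = u_pop
    # memberships of empty levels are irrelevant to J; fill for completeness
    empty = ~populated
    if empty.any():
        d2 = (centers[:, None] - hist.level_values[None, empty]) ** 2
        with np.errstate(divide="ignore"):
            w = np.where(d2 > 0, d2 ** (-1.0 / (m - 1.0)), np.inf)
        w = np.where(np.isinf(w), 1e300, w)
        u[:, empty] = w / w.sum(axis=0, keepdims=True)
    return FuzzyClusterModel(
        C=C, m=m, centers=centers, memberships=u, levels=hist.level_values,
        J=J, iterations=iters, converged=converged, j_history=j_hist,
    )


def fcm_fit_pixelwise(
    img: Image,
    C: int = 2,
    m: float = 2.0,
    tol: float = 1e-4,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyClusterModel:
    """Classical fuzzy C-means over individual pixels.

    Serves as the correctness oracle for :func:`enfcm_fit`; its cost scales
    with the pixel count rather than the number of gray levels, which is why
    the histogram-accelerated variant exists at all.
    """
    if C < 2 or m <= 1:
        raise ValueError("require C >= 2 and m > 1")
    pixels = img.astype_float().ravel()
    values, counts = np.unique(pixels, return_counts=True)
    if values.size < C:
        raise ValueError(f"cannot fit {C} clusters to {values.size} distinct intensities")
    # iterate over the distinct-value list with unit weight expanded as counts:
    # mathematically identical to looping over every pixel, without the memory
    init = _percentile_init(values, counts.astype(np.float64), C)
    centers, u_vals, J, iters, converged, j_hist = _fcm_alternate(
        values, counts.astype(np.float64), C, m, tol, max_iter, init
    )
    return FuzzyClusterModel(
        C=C, m=m, centers=centers, memberships=u_vals, levels=values,
        J=J, iterations=iters, converged=converged, j_history=j_hist,
    )


def membership_threshold(model: FuzzyClusterModel, hist: IntensityHistogram) -> float:
    """Smallest gray level whose foreground membership reaches 0.5.

    The foreground cluster is the one with the larger center.  For C=2 and
    m=2 this cut-off coincides with the midpoint of the two centers.
    """
    if model.C != 2:
        raise ValueError("membership threshold is defined for the 2-cluster model")
    if model.memberships.size == 0:
        raise RuntimeError("model is not fitted")
    c_lo, c_hi = float(model.centers[0]), float(model.centers[1])
    if abs(c_hi - c_lo) < 1e-12:
        raise ValueError("degenerate model: coincident cluster centers")
    fg = int(np.argmax(model.centers))
    levels = hist.level_values
    d2 = (model.centers[:, None] - levels[None, :]) ** 2
    with np.errstate(divide="ignore"):
        w = np.where(d2 > 0, d2 ** (-1.0 / (model.m - 1.0)), np.inf)
    # exact-hit levels take membership 1 in their cluster
    u_fg = np.empty(levels.size)
    hit = np.isinf(w).any(axis=0)
    u_fg[~hit] = w[fg, ~hit] / w[:, ~hit].sum(axis=0)
    u_fg[hit] = np.isinf(w[fg, hit]).astype(float)
    above = np.flatnonzero(u_fg >= 0.5)
    if above.size == 0:
        return float(levels[-1])
    return float(levels[above[0]])


def mask_cells(img: Image, params: EnFCMParams | None = None) -> tuple[BinaryMask, float]:
    """EnFCM foreground mask of the preprocessed cytoplasm channel.

    Returns the mask together with the gray-value cut-off used, so runs can
    log the threshold per image.
    """
    p = params or EnFCMParams()
    hist = image_histogram(img, q=p.q)
    model = enfcm_fit(hist, C=p.C, m=p.m, tol=p.tol, max_iter=p.max_iter, seed=p.seed)
    thr = membership_threshold(model, hist)
    mask = BinaryMask((img.astype_float() >= thr).astype(np.uint8))
    return mask, thr


def mask_cells_otsu(img: Image) -> tuple[BinaryMask, float]:
    """Comparator: conventional Otsu threshold on the cytoplasm channel."""
    pixels = img.astype_float()
    if float(pixels.min()) == float(pixels.max()):
        raise DegenerateHistogramError("constant image cannot be Otsu-thresholded")
    thr = float(threshold_otsu(pixels))
    return BinaryMask((pixels > thr).astype(np.uint8)), thr
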