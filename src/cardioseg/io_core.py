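"""Domain containers and raster/tabular I/O shared by the whole pipeline.

The pipeline operates on two-channel fluorescence montages: a nuclear stain
(DAPI-like) and a cytoplasmic marker (sarcomeric α-actinin-like).  All rasters
are single-plane grayscale TIFFs; per-cell measurements travel as CSV tables.

Conventions: row-major arrays, origin at the top-left pixel, 0-based indices;
areas and lengths are expressed in pixels.  Intensities are carried as the raw
stored integers until a stage explicitly normalizes them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Image",
    "BinaryMask",
    "LabelMask",
    "ChannelPair",
    "CellRecord",
    "read_image",
    "write_image",
    "write_label_mask",
    "read_label_mask",
    "write_cell_table",
    "read_cell_table",
]

ChannelTag = Literal["nuclear", "cytoplasm"]


@dataclasses.dataclass
class Image:
    """A single-channel 2D intensity raster.

    Parameters
    ----------
    pixels
        2D array of non-negative intensities (arbitrary units).
    bit_depth
        Nominal quantization of the source data, 8 or 16.  Intensities must
        fit in ``[0, 2**bit_depth - 1]``.
    channel_tag
        Which stain the raster carries: ``"nuclear"`` or ``"cytoplasm"``.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    channel_tag: ChannelTag = "cytoplasm"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"Image must be 2D with positive extent, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.channel_tag not in ("nuclear", "cytoplasm"):
            raise ValueError(f"unknown channel_tag {self.channel_tag!r}")
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise ValueError("Image intensities must be non-negative")
        if self.pixels.size and float(self.pixels.max()) > self.max_value:
            raise ValueError(
                f"intensity {float(self.pixels.max())} exceeds {self.bit_depth}-bit range"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        """Full-scale value for the nominal bit depth."""
        return (1 << self.bit_depth) - 1

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def with_pixels(self, pixels: np.ndarray) -> "Image":
        """Copy of this image carrying new pixel data (same depth and tag)."""
        return Image(pixels, bit_depth=self.bit_depth, channel_tag=self.channel_tag)


@dataclasses.dataclass
class BinaryMask:
    """2D array of {0,1} marking foreground pixels."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("BinaryMask must be 2D")
        if arr.dtype != np.uint8 or not np.isin(arr, (0, 1)).all():
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1, True, False)).all():
                raise ValueError(f"BinaryMask values must be 0/1, found {vals[:5]}")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def as_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclasses.dataclass
class LabelMask:
    """Integer raster assigning each pixel to background (0) or an object id.

    Object ids are kept as a contiguous range ``1..K`` (relabeled on
    construction unless already contiguous); every object is non-empty.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("LabelMask must be 2D")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("LabelMask requires integer labels")
            arr = np.round(arr).astype(np.int64)
        if arr.size and arr.min() < 0:
            raise ValueError("LabelMask labels must be non-negative")
        ids = np.unique(arr)
        ids = ids[ids > 0]
        if ids.size and (ids[-1] != ids.size):
            # compress ids to 1..K preserving order and the pixel partition
            lut = np.zeros(int(ids[-1]) + 1, dtype=np.int64)
            lut[ids] = np.arange(1, ids.size + 1)
            arr = lut[arr]
        self.pixels = arr.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def n_objects(self) -> int:
        return int(self.pixels.max()) if self.pixels.size else 0

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, self.n_objects + 1)

    def as_binary(self) -> BinaryMask:
        return BinaryMask((self.pixels > 0).astype(np.uint8))

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "LabelMask":
        return cls(np.zeros(shape, dtype=np.int64))


@dataclasses.dataclass
class ChannelPair:
    """The nuclear/cytoplasm channel pairing of one field of view."""

    nuclear: Image
    cytoplasm: Image

    def __post_init__(self) -> None:
        if self.nuclear.shape != self.cytoplasm.shape:
            raise ValueError(
                f"channel shapes differ: nuclear {self.nuclear.shape} "
                f"vs cytoplasm {self.cytoplasm.shape}"
            )
        if self.nuclear.channel_tag != "nuclear":
            self.nuclear = Image(self.nuclear.pixels, self.nuclear.bit_depth, "nuclear")
        if self.cytoplasm.channel_tag != "cytoplasm":
            self.cytoplasm = Image(self.cytoplasm.pixels, self.cytoplasm.bit_depth, "cytoplasm")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear.shape


@dataclasses.dataclass
class CellRecord:
    """Per-cell phenotype vector keyed by cell id, image id and condition."""

    cell_id: int
    image_id: str
    condition: str
    features: dict[str, float]

    def __post_init__(self) -> None:
        if self.cell_id <= 0:
            raise ValueError("cell_id must be positive")
        self.features = {str(k): float(v) for k, v in self.features.items()}


class FormatError(ValueError):
    """Raised for rasters or tables that violate the supported formats."""


def read_image(path: str | Path, channel_tag: ChannelTag = "cytoplasm") -> Image:
    """Read a single-plane grayscale TIFF as an :class:`Image`.

    Bit depth is inferred from the stored dtype (uint8 → 8, uint16 → 16); no
    intensity rescaling is performed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: expected a single-plane grayscale TIFF, got shape "
            f"{arr.shape} (offending extra axis of length {arr.shape[0] if arr.ndim > 2 else arr.shape[-1]})"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(f"{path.name}: unsupported TIFF dtype {arr.dtype}; need uint8 or uint16")
    return Image(arr, bit_depth=depth, channel_tag=channel_tag)


def write_image(img: Image, path: str | Path) -> Path:
    """Write an :class:`Image` as an 8- or 16-bit grayscale TIFF."""
    path = Path(path)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    tifffile.imwrite(str(path), np.asarray(np.round(img.pixels), dtype=dtype))
    return path


def write_label_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a label mask as a 16-bit TIFF with pixel values equal to label ids."""
    if mask.n_objects > 0xFFFF:
        raise ValueError(f"label mask has {mask.n_objects} objects; 16-bit TIFF holds at most 65535")
    path = Path(path)
    tifffile.imwrite(str(path), mask.pixels.astype(np.uint16))
    return path


def read_label_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: label mask TIFF must be single-plane, got {arr.shape}")
    return LabelMask(arr.astype(np.int64))


def _feature_columns(records: Sequence[CellRecord], feature_order: Sequence[str] | None) -> list[str]:
    names = set(records[0].features) if records else set()
    for rec in records:
        if set(rec.features) != names:
            raise ValueError(
                "inconsistent feature sets across records: "
                f"{sorted(names ^ set(rec.features))}"
            )
    if feature_order is not None:
        ordered = [f for f in feature_order if f in names]
        ordered += sorted(names - set(ordered))
        return ordered
    return sorted(names)


def write_cell_table(
    records: Sequence[CellRecord],
    path: str | Path,
    feature_order: Sequence[str] | None = None,
) -> Path:
    """Write per-cell records as a CSV: image_id, condition, cell_id, features.

    Feature columns follow ``feature_order`` (the phenotype registry) where
    given; floats are serialized at full round-trip precision.
    """
    path = Path(path)
    cols = _feature_columns(records, feature_order)
    rows = [
        {"image_id": r.image_id, "condition": r.condition, "cell_id": r.cell_id, **r.features}
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["image_id", "condition", "cell_id", *cols])
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_cell_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so serialized floats come back bit-identical
    return pd.read_csv(path, float_precision="round_trip")


def records_from_frame(df: pd.DataFrame) -> list[CellRecord]:
    """Rebuild :class:`CellRecord` objects from a cell-table DataFrame."""
    meta = {"image_id", "condition", "cell_id"}
    feats = [c for c in df.columns if c not in meta]
    return [
        CellRecord(
            cell_id=int(row["cell_id"]),
            image_id=str(row["image_id"]),
            condition=str(row["condition"]),
            features={f: float(row[f]) for f in feats},
        )
        for _, row in df.iterrows()
    ]
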