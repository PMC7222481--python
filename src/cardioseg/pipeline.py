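"""End-to-end orchestration with a YAML config, structured logs and reproducible runs.

The segmentation chain per field of view: preprocess both channels →
detect nucleus seeds → EnFCM cell mask → augment mask with seeds →
propagate seeds into cells.  Feature extraction and evaluation consume the
resulting masks.  For fixed config and seed every output file is
byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import io_core, phenotype
from .cell_mask import EnFCMParams, mask_cells
from .io_core import BinaryMask, ChannelPair, Image, LabelMask
from .nuclei_seg import NucleiParams, detect_nuclei
from .preprocess import PreprocessParams, preprocess_pair
from .propagate import PropagationParams, propagate_cells
from .synthetic import DoseEffect, SceneParams, generate_scene

__all__ = ["PipelineConfig", "run_segment", "segment_pair", "run_features", "run_evaluate"]

CONFIG_VERSION = 1

_BLOCKS = {
    "preprocess": PreprocessParams,
    "nuclei_seg": NucleiParams,
    "cell_mask": EnFCMParams,
    "propagate": PropagationParams,
    "synthetic": SceneParams,
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    preprocess: PreprocessParams = dataclasses.field(default_factory=PreprocessParams)
    nuclei_seg: NucleiParams = dataclasses.field(default_factory=NucleiParams)
    cell_mask: EnFCMParams = dataclasses.field(default_factory=EnFCMParams)
    propagate: PropagationParams = dataclasses.field(default_factory=PropagationParams)
    synthetic: SceneParams = dataclasses.field(default_factory=SceneParams)
    seed: int = 0
    log_level: str = "info"
    version: int = CONFIG_VERSION

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for name, block_cls in _BLOCKS.items():
            if name in data:
                block = dict(data[name])
                if name == "synthetic" and "dose_effect" in block and isinstance(block["dose_effect"], Mapping):
                    block["dose_effect"] = DoseEffect(**block["dose_effect"])
                field_names = {f.name for f in dataclasses.fields(block_cls)}
                bad = set(block) - field_names
                if bad:
                    raise ValueError(f"unknown keys in config block {name!r}: {sorted(bad)}")
                kwargs[name] = block_cls(**block)
        for scalar in ("seed", "log_level", "version"):
            if scalar in data:
                kwargs[scalar] = data[scalar]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        return out

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


def segment_pair(
    pair: ChannelPair, config: PipelineConfig | None = None
) -> tuple[LabelMask, LabelMask, dict[str, Any]]:
    """Segment one channel pair in memory: returns (seeds, cells, log).

    The log records the Otsu and EnFCM thresholds, iteration counts, orphan
    seeds, seedless-component pixels, per-stage wall time and counts — one
    structured entry per stage.
    """
    cfg = config or PipelineConfig()
    log: dict[str, Any] = {"stages": []}

    t0 = time.perf_counter()
    pre = preprocess_pair(pair, cfg.preprocess)
    log["stages"].append({"stage": "preprocess", "seconds": round(time.perf_counter() - t0, 4)})

    t0 = time.perf_counter()
    seeds, otsu_t = detect_nuclei(pre.nuclear, cfg.nuclei_seg, return_threshold=True)
    log["stages"].append({
        "stage": "nuclei", "seconds": round(time.perf_counter() - t0, 4),
        "otsu_threshold": otsu_t, "n_seeds": seeds.n_objects,
    })

    t0 = time.perf_counter()
    if seeds.n_objects == 0:
        cells = LabelMask.empty(pair.shape)
        log["stages"].append({"stage": "cell_mask", "skipped": "no seeds"})
        log["stages"].append({"stage": "propagate", "n_cells": 0})
        return seeds, cells, log
    try:
        cmask, enfcm_t = mask_cells(pre.cytoplasm, cfg.cell_mask)
    except ValueError:
        cmask, enfcm_t = BinaryMask(np.zeros(pair.shape, dtype=np.uint8)), float("nan")
    log["stages"].append({
        "stage": "cell_mask", "seconds": round(time.perf_counter() - t0, 4),
        "enfcm_threshold": enfcm_t, "foreground_px": cmask.foreground_count,
    })

    t0 = time.perf_counter()
    cells, info = propagate_cells(pre.cytoplasm, seeds, cmask, cfg.propagate, return_info=True)
    log["stages"].append({
        "stage": "propagate", "seconds": round(time.perf_counter() - t0, 4),
        "n_cells": cells.n_objects, "orphan_seeds": info["orphan_seeds"],
        "seedless_component_pixels": info["seedless_component_pixels"],
    })
    return seeds, cells, log


def run_segment(
    pair_paths: Sequence[tuple[str | Path, str | Path]],
    config: PipelineConfig | None = None,
    out_dir: str | Path = "cardioseg_out",
) -> list[dict[str, Any]]:
    """Segment a batch of (nuclear_path, cytoplasm_path) TIFF pairs.

    Writes seed and cell label masks plus a JSON run log per image; the
    effective config is archived next to the outputs.  Images stream one at
    a time, so montage-scale inputs never need batch memory.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "effective_config.yaml")
    logs = []
    for nuc_path, cyto_path in pair_paths:
        image_id = Path(cyto_path).stem
        try:
            pair = ChannelPair(
                nuclear=io_core.read_image(nuc_path, "nuclear"),
                cytoplasm=io_core.read_image(cyto_path, "cytoplasm"),
            )
            seeds, cells, log = segment_pair(pair, cfg)
        except Exception as exc:  # annotate failures with the image id
            raise RuntimeError(f"segmentation failed on image {image_id!r}: {exc}") from exc
        io_core.write_label_mask(seeds, out / f"{image_id}_seeds.tif")
        io_core.write_label_mask(cells, out / f"{image_id}_cells.tif")
        log["image_id"] = image_id
        (out / f"{image_id}_log.json").write_text(json.dumps(log, indent=1, sort_keys=True))
        logs.append(log)
    return logs


def run_features(
    mask_paths: Sequence[tuple[str | Path, str | Path]],
    pair_paths: Sequence[tuple[str | Path, str | Path]],
    config: PipelineConfig | None = None,
    out_path: str | Path = "cell_table.csv",
    conditions: Sequence[str] | None = None,
    resume: bool = True,
) -> Path:
    """Measure phenotypes over a batch: one CSV row per cell.

    ``mask_paths`` holds (seed_mask, cell_mask) TIFFs aligned with
    ``pair_paths``.  An existing output is kept untouched when ``resume`` is
    set, so interrupted batches re-run idempotently.
    """
    out_path = Path(out_path)
    if resume and out_path.exists():
        return out_path
    all_records = []
    for i, ((seed_p, cell_p), (nuc_p, cyto_p)) in enumerate(zip(mask_paths, pair_paths)):
        pair = ChannelPair(
            nuclear=io_core.read_image(nuc_p, "nuclear"),
            cytoplasm=io_core.read_image(cyto_p, "cytoplasm"),
        )
        seeds = io_core.read_label_mask(seed_p)
        cells = io_core.read_label_mask(cell_p)
        condition = conditions[i] if conditions else "control"
        records, _summary = phenotype.measure_image(
            cells, pair, seeds, image_id=Path(cyto_p).stem, condition=condition
        )
        all_records.extend(records)
    io_core.write_cell_table(all_records, out_path, feature_order=phenotype.FEATURE_REGISTRY)
    return out_path


def run_evaluate(
    pred_paths: Sequence[str | Path],
    ref_paths: Sequence[str | Path],
    out_path: str | Path = "evaluation.csv",
) -> pd.DataFrame:
    """Pixel P/R/F of predicted vs reference masks, Mean/SEM layout.

    Inputs are label-mask TIFFs; foreground is any nonzero label.  Nucleus
    count correctness is reported alongside when both masks are labeled.
    """
    preds = [io_core.read_label_mask(p) for p in pred_paths]
    refs = [io_core.read_label_mask(p) for p in ref_paths]
    result = ev.evaluate_masks([p.as_binary() for p in preds], [r.as_binary() for r in refs])
    rows = []
    for i, m in enumerate(result.per_image):
        correctness = np.nan
        if refs[i].n_objects > 0:
            correctness = ev.nuclei_correctness(preds[i], refs[i])
        rows.append({"image": i, **m, "object_correctness": correctness})
    rows.append({"image": "Mean", "precision": result.precision, "recall": result.recall,
                 "f_score": result.f_score,
                 "object_correctness": float(np.nanmean([r["object_correctness"] for r in rows]))})
    rows.append({"image": "SEM", **result.sem, "object_correctness": np.nan})
    df = pd.DataFrame(rows)
    df.to_csv(out_path, index=False)
    return df
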