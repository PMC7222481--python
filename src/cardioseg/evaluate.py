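"""Segmentation quality metrics and dose-response statistics.

Pixel-level precision / recall / F-score against reference masks (per-image
then aggregated as mean ± SEM), the one-to-one majority rule for nucleus
count correctness, and the two-sample Kolmogorov–Smirnov comparison of
per-cell feature distributions between treated conditions and vehicle
control (significance at p < 0.05, no multiple-testing correction by
default, matching the screening convention; a Benjamini–Hochberg option is
available).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import BinaryMask, CellRecord, LabelMask

__all__ = [
    "EvaluationResult",
    "KSResult",
    "pixel_prf",
    "evaluate_masks",
    "nuclei_correctness",
    "ks_compare",
    "dose_response_report",
]


@dataclasses.dataclass
class EvaluationResult:
    """Aggregate precision/recall/F with per-image values and SEMs."""

    precision: float
    recall: float
    f_score: float
    per_image: list[dict[str, float]]
    sem: dict[str, float]


@dataclasses.dataclass
class KSResult:
    statistic: float
    p_value: float
    significant: bool


def pixel_prf(pred: BinaryMask, ref: BinaryMask) -> dict[str, float]:
    """Pixelwise precision, recall and F-score of a foreground mask.

    F = 2·recall·precision / (recall + precision).  An all-background
    reference matched by an all-background prediction scores 1 on all three
    by convention.
    """
    if pred.shape != ref.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    p = pred.as_bool()
    r = ref.as_bool()
    tp = float((p & r).sum())
    fp = float((p & ~r).sum())
    fn = float((~p & r).sum())
    if tp + fp + fn == 0:
        return {"precision": 1.0, "recall": 1.0, "f_score": 1.0}
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = (2 * precision * recall / (precision + recall)) if precision + recall > 0 else 0.0
    return {"precision": precision, "recall": recall, "f_score": f}


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


def evaluate_masks(
    preds: Sequence[BinaryMask], refs: Sequence[BinaryMask], pooled: bool = False
) -> EvaluationResult:
    """Per-image metrics aggregated as mean ± SEM across images.

    ``pooled=True`` instead pools TP/FP/FN over all pixels of all images
    before computing the three metrics (SEMs are then 0).
    """
    if len(preds) != len(refs):
        raise ValueError("pred/ref lists must have equal length")
    if not preds:
        raise ValueError("cannot evaluate an empty list of masks")
    if pooled:
        tp = fp = fn = 0.0
        for p_mask, r_mask in zip(preds, refs):
            p, r = p_mask.as_bool(), r_mask.as_bool()
            tp += float((p & r).sum()); fp += float((p & ~r).sum()); fn += float((~p & r).sum())
        precision = tp / (tp + fp) if tp + fp else 1.0
        recall = tp / (tp + fn) if tp + fn else 1.0
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        one = {"precision": precision, "recall": recall, "f_score": f}
        return EvaluationResult(precision, recall, f, [one], {k: 0.0 for k in one})
    per_image = [pixel_prf(p, r) for p, r in zip(preds, refs)]
    agg = {k: float(np.mean([m[k] for m in per_image])) for k in ("precision", "recall", "f_score")}
    sem = {k: _sem(np.array([m[k] for m in per_image])) for k in agg}
    return EvaluationResult(agg["precision"], agg["recall"], agg["f_score"], per_image, sem)


def nuclei_correctness(pred: LabelMask, ref: LabelMask) -> float:
    """Fraction of reference nuclei segmented correctly under a one-to-one majority rule.

    A reference nucleus is correct iff exactly one predicted nucleus claims
    the strict majority (>50 %) of its pixels AND that predicted nucleus
    does not also majority-claim another reference nucleus (which would mean
    the two were merged).
    """
    if pred.shape != ref.shape:
        raise ValueError("mask shapes differ")
    n_ref = ref.n_objects
    if n_ref == 0:
        raise ValueError("reference mask holds no nuclei")
    majority_claimer: dict[int, int | None] = {}
    for rid in range(1, n_ref + 1):
        region = ref.pixels == rid
        claimed = pred.pixels[region]
        total = claimed.size
        claimer: int | None = None
        if total:
            ids, counts = np.unique(claimed[claimed > 0], return_counts=True)
            if ids.size:
                best = int(np.argmax(counts))
                if counts[best] * 2 > total:
                    claimer = int(ids[best])
        majority_claimer[rid] = claimer
    claim_counts: dict[int, int] = {}
    for claimer in majority_claimer.values():
        if claimer is not None:
            claim_counts[claimer] = claim_counts.get(claimer, 0) + 1
    correct = sum(
        1 for claimer in majority_claimer.values()
        if claimer is not None and claim_counts[claimer] == 1
    )
    return correct / n_ref


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_a − ECDF_b| over the pooled sample points."""
    grid = np.sort(np.concatenate([a, b]))
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def _kolmogorov_sf(lam: float, terms: int = 100) -> float:
    """Two-sided asymptotic Kolmogorov survival function Q(λ)."""
    if lam <= 0:
        return 1.0
    s = sum((-1.0) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
            for k in range(1, terms + 1))
    return float(min(1.0, max(0.0, 2.0 * s)))


def ks_compare(treated: Sequence[float], control: Sequence[float], alpha: float = 0.05) -> KSResult:
    """Two-sample Kolmogorov–Smirnov comparison of a treated vs control sample.

    D = sup |ECDF_treated − ECDF_control|.  The p-value is exact when both
    samples hold ≤ 25 observations; otherwise the classic asymptotic
    Kolmogorov distribution is evaluated at λ = √(nm/(n+m)) · D.
    """
    t = np.asarray(treated, dtype=np.float64)
    c = np.asarray(control, dtype=np.float64)
    if t.size < 5 or c.size < 5:
        raise ValueError("KS comparison needs >= 5 observations per sample")
    d = _ks_statistic(t, c)
    if t.size <= 25 and c.size <= 25:
        p = float(stats.ks_2samp(t, c, alternative="two-sided", method="exact").pvalue)
    else:
        en = math.sqrt(t.size * c.size / (t.size + c.size))
        p = _kolmogorov_sf(en * d)
    return KSResult(statistic=d, p_value=p, significant=bool(p < alpha))


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    n = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(pvals)
    out[order] = np.clip(ranked, 0, 1)
    return out


def dose_response_report(
    tables: Mapping[str, Sequence[CellRecord]],
    control_name: str,
    features: Sequence[str] | None = None,
    alpha: float = 0.05,
    bh_correct: bool = False,
    cell_numbers: Mapping[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Per feature × condition summary with KS significance vs control.

    ``tables`` maps condition name → per-cell records pooled over that
    condition's replicate images.  Each row reports mean, SEM, KS D, p and a
    significance flag for one feature under one treated condition.  When
    ``cell_numbers`` (condition → per-replicate cell counts) is given, a
    ``cell_number`` block is added with the mean expressed as % of the
    control mean — the viability read-out.
    """
    if control_name not in tables:
        raise ValueError(f"control condition {control_name!r} missing from tables")
    control_records = list(tables[control_name])
    if not control_records:
        raise ValueError("control condition holds no cells")
    feat_names = list(features) if features is not None else sorted(control_records[0].features)
    rows: list[dict] = []
    for cond, records in tables.items():
        if cond == control_name:
            continue
        for feat in feat_names:
            tr = np.array([r.features[feat] for r in records], dtype=np.float64)
            ct = np.array([r.features[feat] for r in control_records], dtype=np.float64)
            tr = tr[np.isfinite(tr)]
            ct = ct[np.isfinite(ct)]
            if tr.size < 5 or ct.size < 5:
                ks = KSResult(np.nan, np.nan, False)
            else:
                ks = ks_compare(tr, ct, alpha=alpha)
            rows.append({
                "condition": cond, "feature": feat,
                "mean": float(tr.mean()) if tr.size else np.nan,
                "sem": _sem(tr),
                "control_mean": float(ct.mean()) if ct.size else np.nan,
                "ks_D": ks.statistic, "p_value": ks.p_value,
                "significant": ks.significant,
            })
    report = pd.DataFrame(rows)
    if bh_correct and not report.empty:
        finite = report["p_value"].notna()
        adj = report.loc[finite, "p_value"].to_numpy()
        report.loc[finite, "p_value_bh"] = _bh_adjust(adj)
        report.loc[finite, "significant"] = report.loc[finite, "p_value_bh"] < alpha
    if cell_numbers is not None:
        ctrl_counts = np.asarray(cell_numbers[control_name], dtype=np.float64)
        ctrl_mean = float(ctrl_counts.mean())
        extra = []
        for cond, counts in cell_numbers.items():
            arr = np.asarray(counts, dtype=np.float64)
            extra.append({
                "condition": cond, "feature": "cell_number",
                "mean": float(arr.mean()), "sem": _sem(arr),
                "control_mean": ctrl_mean,
                "pct_of_control": 100.0 * float(arr.mean()) / ctrl_mean if ctrl_mean else np.nan,
                "ks_D": np.nan, "p_value": np.nan, "significant": False,
            })
        report = pd.concat([report, pd.DataFrame(extra)], ignore_index=True)
    return report
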