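"""Segmentation metrics (Dice / sensitivity / specificity) and reporting.

Metrics are computed from pixel confusion counts:

    Dice = 2TP / (2TP + FP + FN);  SEN = TP / (TP + FN);  SPE = TN / (FP + TN)

Empty-denominator convention: when the relevant reference set is empty the
metric is 1 if the prediction agrees (also empty) and 0 otherwise.
Reports carry per-slice metrics, per-case means, slice-level global means
and pixel-pooled global metrics — the last two because published tables
rarely state which aggregation they use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import DatasetManifest


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FP + other.FP, self.FN + other.FN, self.TN + other.TN
        )


def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    for name, m in (("pred", pred), ("gt", gt)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary (0/1)")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(p & g)),
        FP=int(np.sum(p & ~g)),
        FN=int(np.sum(~p & g)),
        TN=int(np.sum(~p & ~g)),
    )


def _ratio(num: int, den: int, empty_agrees: bool) -> float:
    if den == 0:
        return 1.0 if empty_agrees else 0.0
    return num / den


def dice(c: ConfusionCounts) -> float:
    return _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, empty_agrees=c.FP == 0)


def sen(c: ConfusionCounts) -> float:
    return _ratio(c.TP, c.TP + c.FN, empty_agrees=c.FP == 0)


def spe(c: ConfusionCounts) -> float:
    return _ratio(c.TN, c.FP + c.TN, empty_agrees=c.FN == 0)


def slice_metrics(pred_mask, gt_mask) -> dict:
    c = confusion(pred_mask, gt_mask)
    return {"dice": dice(c), "sen": sen(c), "spe": spe(c), "counts": c}


def evaluate_dataset(predictions: dict, manifest: DatasetManifest, masks: dict) -> dict:
    """Score one binary prediction per test slice.

    ``predictions`` and ``masks`` map slice keys ``(case_id, slice_index)``
    to binary H x W arrays.  Raises if any manifest slice lacks a
    prediction, listing the missing ids.
    """
    keys = [(e.case_id, e.slice_index) for e in manifest.entries]
    missing = [k for k in keys if k not in predictions]
    if missing:
        raise KeyError(f"missing predictions for slices: {missing}")

    per_slice = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    by_case: dict[str, list[dict]] = {}
    for case_id, idx in keys:
        m = slice_metrics(predictions[(case_id, idx)], masks[(case_id, idx)])
        c = m.pop("counts")
        pooled = pooled + c
        row = {"case_id": case_id, "slice_index": idx, **m,
               "empty_gt": bool(c.TP + c.FN == 0)}
        per_slice.append(row)
        by_case.setdefault(case_id, []).append(row)

    def mean_of(rows, key, skip_empty=False):
        vals = [r[key] for r in rows if not (skip_empty and r["empty_gt"])]
        return float(np.mean(vals)) if vals else float("nan")

    per_case = [
        {
            "case_id": cid,
            "dice": mean_of(rows, "dice"),
            "sen": mean_of(rows, "sen", skip_empty=True),
            "spe": mean_of(rows, "spe"),
            "n_slices": len(rows),
        }
        for cid, rows in by_case.items()
    ]
    report = {
        "per_slice": per_slice,
        "per_case": per_case,
        "global": {
            "slice_mean_dice": mean_of(per_slice, "dice"),
            "slice_mean_sen": mean_of(per_slice, "sen", skip_empty=True),
            "slice_mean_spe": mean_of(per_slice, "spe"),
            "pixel_pooled_dice": dice(pooled),
            "pixel_pooled_sen": sen(pooled),
            "pixel_pooled_spe": spe(pooled),
            "n_slices": len(per_slice),
            "n_empty_gt_slices": sum(r["empty_gt"] for r in per_slice),
        },
    }
    return report


def report_table(report: dict) -> str:
    """Aligned text table: one row per slice, per case, plus the global row."""
    lines = [f"{'id':<28}{'dice':>8}{'sen':>8}{'spe':>8}"]
    for r in report["per_slice"]:
        lines.append(
            f"{r['case_id'] + '/' + str(r['slice_index']):<28}"
            f"{r['dice']:>8.4f}{r['sen']:>8.4f}{r['spe']:>8.4f}"
        )
    for r in report["per_case"]:
        lines.append(
            f"{r['case_id'] + ' (case)':<28}{r['dice']:>8.4f}{r['sen']:>8.4f}{r['spe']:>8.4f}"
        )
    g = report["global"]
    lines.append(
        f"{'GLOBAL (slice mean)':<28}"
        f"{g['slice_mean_dice']:>8.4f}{g['slice_mean_sen']:>8.4f}{g['slice_mean_spe']:>8.4f}"
    )
    return "\n".join(lines)


def save_report(report: dict, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    (out_dir / "report.txt").write_text(report_table(report) + "\n")


def write_overlay(path, image: np.ndarray, pred_mask: np.ndarray, gt_mask: np.ndarray) -> None:
    """RGB overlay PNG: prediction contour green, ground-truth contour red."""
    from PIL import Image
    from skimage.segmentation import find_boundaries

    rgb = np.stack([np.clip(image, 0, 1)] * 3, axis=-1)
    pb = find_boundaries(np.asarray(pred_mask).astype(bool), mode="inner")
    gb = find_boundaries(np.asarray(gt_mask).astype(bool), mode="inner")
    rgb[gb] = [1.0, 0.0, 0.0]
    rgb[pb] = [0.0, 1.0, 0.0]
    Image.fromarray((rgb * 255).astype(np.uint8), mode="RGB").save(path)
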