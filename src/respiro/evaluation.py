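"""Segmentation-quality metrics and annotation handling.

Pixel-level IoU / F1 / accuracy against consensus ground truth, the
consensus itself (pixel-wise AND of two annotators), inter-annotator
agreement, selection of the evaluation subset (images with enough
labelled foreground), stratified dataset splitting, and the per-object
size correlation between predicted and ground-truth instances.

Accuracy is reported but is misleading under the extreme
foreground/background imbalance of these images (a trivial
all-background prediction already scores ~0.99); IoU and F1 are the
informative metrics, and a test documents this caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinaryMask, get_logger
from .objects import LabelMap

logger = get_logger(__name__)


@dataclass
class PixelMetrics:
    iou: float
    f1: float
    accuracy: float
    tp: int
    fp: int
    fn: int
    tn: int
    degenerate: bool = False  # truth and prediction both empty


def pixel_metrics(pred: BinaryMask, truth: BinaryMask) -> PixelMetrics:
    """Confusion counts and IoU / F1 / accuracy for one image pair.

    IoU = TP/(TP+FP+FN), F1 = 2TP/(2TP+FP+FN), accuracy = (TP+TN)/total.
    When truth and prediction are both empty the overlap metrics are
    defined as 1 and flagged degenerate.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p, t = pred.mask, truth.mask
    tp = int(np.logical_and(p, t).sum())
    fp = int(np.logical_and(p, ~t).sum())
    fn = int(np.logical_and(~p, t).sum())
    tn = int(np.logical_and(~p, ~t).sum())
    total = tp + fp + fn + tn
    degenerate = (tp + fp + fn) == 0
    iou = 1.0 if degenerate else tp / (tp + fp + fn)
    f1 = 1.0 if degenerate else 2 * tp / (2 * tp + fp + fn)
    return PixelMetrics(iou, f1, (tp + tn) / total, tp, fp, fn, tn, degenerate)


def consensus_mask(m1: BinaryMask, m2: BinaryMask) -> BinaryMask:
    """Unanimous-consensus ground truth: pixel-wise AND of two annotations."""
    if m1.shape != m2.shape:
        raise ValueError("annotation shapes differ")
    return BinaryMask(np.logical_and(m1.mask, m2.mask), resolution=m1.resolution)


def interannotator_agreement(pairs: list[tuple[BinaryMask, BinaryMask]]) -> dict:
    """Per-image and mean +/- sd agreement (F1, IoU) between two annotators."""
    if not pairs:
        raise ValueError("no annotation pairs")
    per_image = [pixel_metrics(m2, m1) for m1, m2 in pairs]
    f1 = np.array([m.f1 for m in per_image])
    iou = np.array([m.iou for m in per_image])
    return {
        "per_image_f1": f1.tolist(),
        "per_image_iou": iou.tolist(),
        "f1_mean": float(f1.mean()),
        "f1_sd": float(f1.std(ddof=1)) if len(f1) > 1 else 0.0,
        "iou_mean": float(iou.mean()),
        "iou_sd": float(iou.std(ddof=1)) if len(iou) > 1 else 0.0,
    }


def select_eval_subset(
    images_with_truth: list[tuple[object, BinaryMask]],
    min_labeled_px: int = 5000,
) -> dict:
    """Keep images whose ground-truth foreground exceeds ``min_labeled_px``.

    Images at or below the bound (mostly background / bubbles / dead
    material) are evaluated separately, because overlap metrics on
    near-empty truths are dominated by degenerate cases.
    """
    kept, excluded = [], []
    for item, truth in images_with_truth:
        (kept if truth.area_px > min_labeled_px else excluded).append((item, truth))
    return {
        "subset": kept,
        "excluded": excluded,
        "n_in": len(kept),
        "n_out": len(excluded),
    }


def split_dataset(
    n_images: int,
    fractions: tuple[float, float, float] = (0.85, 0.10, 0.05),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled disjoint train/validation/test index split.

    Train and validation sizes are ``round(n * fraction)``; test takes
    the remainder, so 827 images at 85/10/5 give (703, 83, 41).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = round(n_images * fractions[0])
    n_val = round(n_images * fractions[1])
    n_test = n_images - n_train - n_val
    if n_train < 0 or n_val < 0 or n_test < 0:
        raise ValueError(f"n = {n_images} too small for fractions {fractions}")
    if n_images and n_train == 0:
        raise ValueError("training split is empty")
    perm = np.random.default_rng(seed).permutation(n_images)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def object_size_correlation(pred_lm: LabelMap, truth_lm: LabelMap) -> dict:
    """Per-object area agreement between predicted and true instances.

    Truth objects match a predicted object by maximal pixel overlap
    (greedy by overlap, injective); a truth object matches only if the
    overlap covers >= 50% of its area. R^2 comes from an ordinary
    least-squares fit with intercept on the matched (truth_area,
    pred_area) pairs. With fewer than 2 matched pairs R^2 is undefined
    (NaN, flagged).
    """
    if pred_lm.labels.shape != truth_lm.labels.shape:
        raise ValueError("label map shapes differ")
    nt, npred = truth_lm.n_objects, pred_lm.n_objects
    overlap = np.zeros((nt + 1, npred + 1), dtype=np.int64)
    np.add.at(overlap, (truth_lm.labels, pred_lm.labels), 1)
    truth_areas = overlap[1:, :].sum(axis=1)
    pairs_t, pairs_p = [], []
    used_pred: set[int] = set()
    order = np.argsort(overlap[1:, 1:], axis=None, kind="stable")[::-1]
    matched_truth: set[int] = set()
    for flat in order:
        i, j = divmod(int(flat), npred)
        ov = overlap[i + 1, j + 1]
        if ov == 0:
            break
        if i in matched_truth or j in used_pred:
            continue
        if ov < 0.5 * truth_areas[i]:
            continue
        matched_truth.add(i)
        used_pred.add(j)
        pairs_t.append(int(truth_areas[i]))
        pairs_p.append(int((pred_lm.labels == j + 1).sum()))
    unmatched_truth = nt - len(matched_truth)
    unmatched_pred = npred - len(used_pred)
    if len(pairs_t) < 2:
        return {
            "truth_areas": pairs_t, "pred_areas": pairs_p, "r2": float("nan"),
            "slope": float("nan"), "intercept": float("nan"),
            "n_matched": len(pairs_t),
            "unmatched_truth": unmatched_truth, "unmatched_pred": unmatched_pred,
            "defined": False,
        }
    x = np.asarray(pairs_t, dtype=np.float64)
    y = np.asarray(pairs_p, dtype=np.float64)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot
    return {
        "truth_areas": pairs_t, "pred_areas": pairs_p, "r2": float(r2),
        "slope": float(slope), "intercept": float(intercept),
        "n_matched": len(pairs_t),
        "unmatched_truth": unmatched_truth, "unmatched_pred": unmatched_pred,
        "defined": True,
    }


def evaluation_report(
    items: list[tuple[str, BinaryMask, BinaryMask]],
    min_labeled_px: int = 5000,
) -> pd.DataFrame:
    """Per-image metric rows plus "all" and "viable-subset" summary rows.

    ``items`` are (name, prediction, truth) triples. The viable subset
    keeps images with truth foreground > min_labeled_px.
    """
    rows = []
    for name, pred, truth in items:
        m = pixel_metrics(pred, truth)
        rows.append(dict(image=name, kind="image", iou=m.iou, f1=m.f1,
                         accuracy=m.accuracy, tp=m.tp, fp=m.fp, fn=m.fn, tn=m.tn,
                         labeled_px=truth.area_px, degenerate=m.degenerate))
    df = pd.DataFrame(rows)
    summaries = []
    for kind, sel in (
        ("summary_all", df),
        ("summary_viable", df[df["labeled_px"] > min_labeled_px]),
    ):
        if len(sel):
            summaries.append(dict(
                image="", kind=kind,
                iou=sel["iou"].mean(), f1=sel["f1"].mean(),
                accuracy=sel["accuracy"].mean(),
                tp=sel["tp"].sum(), fp=sel["fp"].sum(),
                fn=sel["fn"].sum(), tn=sel["tn"].sum(),
                labeled_px=sel["labeled_px"].sum(), degenerate=False,
            ))
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
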