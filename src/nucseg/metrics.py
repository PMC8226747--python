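"""Object-level and pixel-level nuclear-segmentation metrics.

Object level: precision / recall / F1 over detected instances with a true
positive declared at 50% overlap (IoU >= 0.5 by default; a >=50%-of-GT
coverage rule is available).  Pixel level: the Dice coefficient of the
foreground unions and the aggregated Jaccard index (AJI), which sums matched
intersections over matched unions plus all unmatched predicted pixels, so
both over- and under-segmentation depress it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "InstanceMask",
    "MatchResult",
    "MetricReport",
    "label_components",
    "instance_sizes",
    "pairwise_intersections",
    "match_objects",
    "object_prf",
    "dice",
    "aji",
    "evaluate_masks",
    "evaluate_dirs",
]

_EIGHT = np.ones((3, 3), dtype=int)


def _as_labels(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("instance mask must be 2-D")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("instance mask must be integer-labeled")
    if arr.min() < 0:
        raise ValueError("instance labels must be non-negative")
    return arr


def label_components(binary: np.ndarray) -> np.ndarray:
    """8-connected components of a binary mask, labeled 1..K in raster order
    of each component's first pixel."""
    arr = np.asarray(binary)
    lab, k = ndimage.label(arr != 0, structure=_EIGHT)
    if k == 0:
        return lab.astype(np.int32)
    # scipy assigns labels in raster order already; enforce it regardless
    first = {}
    flat = lab.reshape(-1)
    nz = np.flatnonzero(flat)
    order = []
    for i in nz:
        v = flat[i]
        if v not in first:
            first[v] = i
            order.append(v)
    remap = np.zeros(k + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[lab]


def relabel_sequential(mask: np.ndarray) -> np.ndarray:
    """Compact arbitrary non-negative labels to a contiguous 0..K set."""
    arr = _as_labels(mask)
    values = np.unique(arr)
    remap = np.zeros(int(values.max()) + 1, dtype=np.int32)
    remap[values[values > 0]] = np.arange(1, np.count_nonzero(values > 0) + 1)
    return remap[arr]


InstanceMask = np.ndarray  # H x W integer labels, 0 = background


def instance_sizes(mask: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(mask.reshape(-1), minlength=k + 1)[: k + 1]


def pairwise_intersections(gt: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """(K_gt+1) x (K_pred+1) contingency table of pixel overlaps."""
    kg, kp = int(gt.max()), int(pred.max())
    joint = gt.astype(np.int64) * (kp + 1) + pred
    counts = np.bincount(joint.reshape(-1), minlength=(kg + 1) * (kp + 1))
    return counts.reshape(kg + 1, kp + 1)


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)


def match_objects(gt: np.ndarray, pred: np.ndarray, threshold: float = 0.5,
                  rule: str = "iou") -> MatchResult:
    """Greedy one-to-one instance matching by descending overlap score.

    ``rule="iou"``: score is IoU and a pair is a true positive iff
    IoU >= threshold.  ``rule="gt-coverage"``: score is
    |G∩P| / |G| (fraction of the ground-truth object covered).  Ties are
    broken by (gt id, pred id) order; unmatched predictions are false
    positives, unmatched ground-truth objects false negatives.
    """
    gt = relabel_sequential(gt)
    pred = relabel_sequential(pred)
    if gt.shape != pred.shape:
        raise ValueError("masks must have the same shape")
    if rule not in ("iou", "gt-coverage"):
        raise ValueError(f"unknown match rule {rule!r}")
    kg, kp = int(gt.max()), int(pred.max())
    inter = pairwise_intersections(gt, pred)
    gsz = instance_sizes(gt, kg)
    psz = instance_sizes(pred, kp)
    candidates = []
    for i in range(1, kg + 1):
        for j in range(1, kp + 1):
            ov = inter[i, j]
            if ov == 0:
                continue
            if rule == "iou":
                score = ov / (gsz[i] + psz[j] - ov)
            else:
                score = ov / gsz[i]
            if score >= threshold:
                candidates.append((-score, i, j))
    candidates.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for negscore, i, j in candidates:
        if i in used_g or j in used_p:
            continue
        used_g.add(i)
        used_p.add(j)
        pairs.append((i, j, -negscore))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=kp - tp, fn=kg - tp, pairs=pairs)


def object_prf(match: MatchResult) -> tuple[float, float, float]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN);
    zero denominators yield 0."""
    tp, fp, fn = match.tp, match.fp, match.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return precision, recall, f1


def dice(gt: np.ndarray, pred: np.ndarray) -> float:
    """Foreground Dice 2|G∩S| / (|G|+|S|); two empty masks score 1."""
    g = np.asarray(gt) > 0
    s = np.asarray(pred) > 0
    if g.shape != s.shape:
        raise ValueError("masks must have the same shape")
    denom = int(g.sum()) + int(s.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((g & s).sum()) / denom


def aji(gt: np.ndarray, pred: np.ndarray) -> float:
    """Aggregated Jaccard index.

    Walking ground-truth instances in id order, each is matched to the
    still-unused predicted instance maximizing the Jaccard index (ties to
    the lower pred id; no overlap leaves the instance unmatched).  AJI is
    the summed matched intersections divided by the summed matched unions,
    unmatched GT pixels, and unmatched predicted pixels.  Two empty masks
    score 1.
    """
    gt = relabel_sequential(gt)
    pred = relabel_sequential(pred)
    if gt.shape != pred.shape:
        raise ValueError("masks must have the same shape")
    kg, kp = int(gt.max()), int(pred.max())
    if kg == 0 and kp == 0:
        return 1.0
    inter = pairwise_intersections(gt, pred)
    gsz = instance_sizes(gt, kg)
    psz = instance_sizes(pred, kp)
    used = np.zeros(kp + 1, dtype=bool)
    num = 0
    den = 0
    for i in range(1, kg + 1):
        best_j, best_jac = 0, -1.0
        for j in range(1, kp + 1):
            if used[j] or inter[i, j] == 0:
                continue
            jac = inter[i, j] / (gsz[i] + psz[j] - inter[i, j])
            if jac > best_jac:
                best_j, best_jac = j, jac
        if best_j:
            used[best_j] = True
            num += int(inter[i, best_j])
            den += int(gsz[i] + psz[best_j] - inter[i, best_j])
        else:
            den += int(gsz[i])
    den += int(psz[1:][~used[1:]].sum())
    return num / den if den else 1.0


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    dice: float
    aji: float

    def as_dict(self) -> dict[str, float]:
        return {"precision": self.precision, "recall": self.recall,
                "f1": self.f1, "dice": self.dice, "aji": self.aji}


def evaluate_masks(gt: np.ndarray, pred: np.ndarray,
                   threshold: float = 0.5, rule: str = "iou") -> MetricReport:
    """All five metrics for one ground-truth / prediction instance pair."""
    p, r, f1 = object_prf(match_objects(gt, pred, threshold, rule))
    return MetricReport(precision=p, recall=r, f1=f1,
                        dice=dice(gt, pred), aji=aji(gt, pred))


def evaluate_dirs(gt_dir, pred_dir, out_csv=None, out_json=None,
                  threshold: float = 0.5, rule: str = "iou") -> dict:
    """Evaluate paired mask files (matched by filename stem) and report
    per-image metrics plus the macro average."""
    from .imgio import read_instance_mask

    gt_dir, pred_dir = Path(gt_dir), Path(pred_dir)
    exts = (".png", ".tif", ".tiff")
    gt_files = {p.stem: p for p in sorted(gt_dir.iterdir())
                if p.suffix.lower() in exts}
    pred_files = {p.stem: p for p in sorted(pred_dir.iterdir())
                  if p.suffix.lower() in exts}
    missing = sorted(set(gt_files) ^ set(pred_files))
    if missing:
        raise ValueError(f"unpaired mask files: {missing}")
    per_image = {}
    for stem in sorted(gt_files):
        gt = read_instance_mask(gt_files[stem])
        pred = read_instance_mask(pred_files[stem])
        per_image[stem] = evaluate_masks(gt, pred, threshold, rule).as_dict()
    keys = ("precision", "recall", "f1", "dice", "aji")
    macro = {k: float(np.mean([m[k] for m in per_image.values()]))
             for k in keys} if per_image else {}
    report = {"per_image": per_image, "macro": macro}
    if out_csv:
        with open(out_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", *keys])
            for stem, m in per_image.items():
                writer.writerow([stem] + [f"{m[k]:.6f}" for k in keys])
            if macro:
                writer.writerow(["macro"] + [f"{macro[k]:.6f}" for k in keys])
    if out_json:
        Path(out_json).write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
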