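"""Point-based detection evaluation.

The detector emits image coordinates with confidences, not boxes, so
correctness is judged by pixel distance rather than intersection over
union: a prediction is potentially correct if it falls within
``dist_threshold`` pixels (50 by default) of the centroid of the *closest*
ground-truth box. If that ground truth is still unmatched and the classes
agree (or both are fly classes, in the class-agnostic "both" mode) it is a
true positive; otherwise a false positive. Ground truths never claimed are
false negatives. Precision = Tp/(Tp+Fp), recall = Tp/(Tp+Fn); sweeping the
confidence threshold yields a precision-recall curve summarised by its
trapezoidal area (AUC).

Bycatch boxes are excluded from matching — they are neither targets nor
misses — but false positives landing near a bycatch centroid are tallied
separately, since on real traps bycatch is the dominant source of false
detections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations_io import (AnnotatedImage, BBox, Detection, FLY_CLASSES,
                             box_centroid)

SUMMARY_ROWS = (("DSF", "Female (DSF)"), ("DSM", "Male (DSM)"),
                ("Both", "Both"))


@dataclass(frozen=True)
class MatchConfig:
    dist_threshold: float = 50.0  # px; matching radius around GT centroids
    class_mode: str = "per_class"  # "per_class" | "both"

    def __post_init__(self):
        if self.dist_threshold <= 0:
            raise ValueError("dist_threshold must be > 0")
        if self.class_mode not in ("per_class", "both"):
            raise ValueError("class_mode must be 'per_class' or 'both'")


@dataclass
class MatchReport:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]]  # (detection index, ground-truth index)
    confidence_threshold: float
    fp_on_bycatch: int = 0


@dataclass
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float


# --------------------------------------------------------------------------
# Matching
# --------------------------------------------------------------------------

def match_detections(dets: Sequence[Detection], gts: Sequence[BBox],
                     cfg: MatchConfig, confidence_threshold: float = 0.0
                     ) -> MatchReport:
    """Greedy one-to-one assignment of detections to ground-truth centroids.

    Detections at or above the confidence threshold are processed in
    descending confidence (ties keep insertion order). Each looks only at
    its *nearest* fly-class ground-truth centroid: too far, already
    claimed, or the wrong class all make it a false positive.
    """
    fly = [(i, b) for i, b in enumerate(gts) if b.label in FLY_CLASSES]
    bc_cents = [box_centroid(b) for b in gts if b.label not in FLY_CLASSES]
    cents = [box_centroid(b) for _, b in fly]

    kept = [(i, d) for i, d in enumerate(dets)
            if d.confidence >= confidence_threshold]
    kept.sort(key=lambda item: -item[1].confidence)  # stable: ties keep order

    matched = [False] * len(fly)
    tp = fp = fp_bc = 0
    pairs: list[tuple[int, int]] = []
    for det_idx, d in kept:
        nearest, nd = -1, math.inf
        for j, (cx, cy) in enumerate(cents):
            dist = math.hypot(d.x - cx, d.y - cy)
            if dist < nd:
                nearest, nd = j, dist
        ok = nearest >= 0 and nd <= cfg.dist_threshold
        if ok and not matched[nearest]:
            gt_label = fly[nearest][1].label
            if cfg.class_mode == "both" or d.pred_class == gt_label:
                matched[nearest] = True
                tp += 1
                pairs.append((det_idx, fly[nearest][0]))
                continue
        fp += 1
        if any(math.hypot(d.x - cx, d.y - cy) <= cfg.dist_threshold
               for cx, cy in bc_cents):
            fp_bc += 1
    fn = len(fly) - tp
    return MatchReport(tp=tp, fp=fp, fn=fn, pairs=pairs,
                       confidence_threshold=confidence_threshold,
                       fp_on_bycatch=fp_bc)


def _match_pooled(groups: Sequence[tuple[Sequence[Detection], Sequence[BBox]]],
                  cfg: MatchConfig, threshold: float) -> MatchReport:
    """Sum per-image match reports at one confidence threshold."""
    tp = fp = fn = fp_bc = 0
    for dets, gts in groups:
        r = match_detections(dets, gts, cfg, threshold)
        tp, fp, fn, fp_bc = tp + r.tp, fp + r.fp, fn + r.fn, fp_bc + r.fp_on_bycatch
    return MatchReport(tp=tp, fp=fp, fn=fn, pairs=[],
                       confidence_threshold=threshold, fp_on_bycatch=fp_bc)


# --------------------------------------------------------------------------
# Precision-recall curves
# --------------------------------------------------------------------------

def pooled_pr_curve(groups: Sequence[tuple[Sequence[Detection], Sequence[BBox]]],
                    cfg: MatchConfig) -> PRCurve:
    """PR curve over detections pooled across images (micro-averaged)."""
    n_gt = sum(len([b for b in gts if b.label in FLY_CLASSES])
               for _, gts in groups)
    if n_gt == 0:
        raise ValueError("recall undefined: no fly ground truths in scope")
    confs = sorted({d.confidence for dets, _ in groups for d in dets},
                   reverse=True)
    thresholds = confs + ([0.0] if 0.0 not in confs else [])
    precision, recall = [], []
    for t in thresholds:
        r = _match_pooled(groups, cfg, t)
        precision.append(r.tp / (r.tp + r.fp) if (r.tp + r.fp) else 1.0)
        recall.append(r.tp / (r.tp + r.fn))
    precision = np.asarray(precision, dtype=float)
    recall = np.asarray(recall, dtype=float)
    # thresholds descend, so recall ascends; anchor the curve at recall 0
    rec_a = np.concatenate([[0.0], recall])
    prec_a = np.concatenate([[precision[0] if len(precision) else 1.0],
                             precision])
    order = np.argsort(rec_a, kind="stable")
    auc = float(np.trapezoid(prec_a[order], rec_a[order]))
    auc = min(max(auc, 0.0), 1.0)
    return PRCurve(thresholds=np.asarray(thresholds), precision=precision,
                   recall=recall, auc=auc)


def pr_curve(dets: Sequence[Detection], gts: Sequence[BBox],
             cfg: MatchConfig) -> PRCurve:
    """PR curve for a single image (thresholds at each unique confidence)."""
    return pooled_pr_curve([(dets, gts)], cfg)


def count_curves(dets: Sequence[Detection], gts: Sequence[BBox],
                 cfg: MatchConfig, threshold_grid: Sequence[float]
                 ) -> pd.DataFrame:
    """Tp/Fp/Fn (and Fp-on-bycatch) per confidence threshold."""
    rows = []
    for t in threshold_grid:
        r = match_detections(dets, gts, cfg, t)
        rows.append({"threshold": t, "tp": r.tp, "fp": r.fp, "fn": r.fn,
                     "fp_on_bycatch": r.fp_on_bycatch})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Dataset-level evaluation
# --------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Per-class PR curves plus the three-row AUC summary."""

    curves: dict[str, PRCurve]
    n_ground_truth: dict[str, int] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [{"sex": label, "auc": round(self.curves[key].auc, 3)}
                for key, label in SUMMARY_ROWS if key in self.curves]
        return pd.DataFrame(rows)


def evaluate_detections(dets_by_image: dict[str, list[Detection]],
                        annotations: Sequence[AnnotatedImage],
                        cfg: MatchConfig | None = None) -> EvalResult:
    """Evaluate pooled detections against annotations, per sex and combined.

    The female and male curves match same-class detections against
    same-class ground truths; "Both" pools the fly classes under
    class-agnostic matching.
    """
    cfg = cfg or MatchConfig()
    per_class_cfg = MatchConfig(cfg.dist_threshold, "per_class")
    both_cfg = MatchConfig(cfg.dist_threshold, "both")
    curves: dict[str, PRCurve] = {}
    n_gt: dict[str, int] = {}
    for cls in FLY_CLASSES:
        groups = []
        for ann in annotations:
            dets = [d for d in dets_by_image.get(ann.image_id, [])
                    if d.pred_class == cls]
            gts = [b for b in ann.boxes if b.label == cls]
            groups.append((dets, gts))
        n_gt[cls] = sum(len(g) for _, g in groups)
        curves[cls] = pooled_pr_curve(groups, per_class_cfg)
    groups = [(dets_by_image.get(ann.image_id, []), ann.fly_boxes())
              for ann in annotations]
    n_gt["Both"] = sum(len(g) for _, g in groups)
    curves["Both"] = pooled_pr_curve(groups, both_cfg)
    return EvalResult(curves=curves, n_ground_truth=n_gt)


def evaluate_dataset(model, samples, cfg: MatchConfig | None = None,
                     min_confidence: float | None = None) -> EvalResult:
    """Run the detector over (image, annotation) pairs, then evaluate."""
    from .grid_detector import DEFAULT_CONFIDENCE_FLOOR, detect_image

    if not samples:
        raise ValueError("test set must be non-empty")
    floor = DEFAULT_CONFIDENCE_FLOOR if min_confidence is None else min_confidence
    dets_by_image = {}
    anns = []
    for image, ann in samples:
        dets, _ = detect_image(model, image, image_id=ann.image_id,
                               min_confidence=floor)
        dets_by_image[ann.image_id] = dets
        anns.append(ann)
    return evaluate_detections(dets_by_image, anns, cfg)


# --------------------------------------------------------------------------
# Plots
# --------------------------------------------------------------------------

_CURVE_COLORS = {"DSF": "#d4a017", "DSM": "#1f5fb4", "Both": "#333333"}


def plot_pr_curves(result: EvalResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for key, label in SUMMARY_ROWS:
        if key not in result.curves:
            continue
        c = result.curves[key]
        ax.plot(c.recall, c.precision, color=_CURVE_COLORS[key],
                label=f"{label} (AUC={c.auc:.3f})")
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_count_curves(tables: dict[str, pd.DataFrame],
                      totals: dict[str, int], path) -> None:
    """Tp/Fp/Fn vs threshold per class; dashed line marks the GT total."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = list(tables)
    fig, axes = plt.subplots(1, len(keys), figsize=(4 * len(keys), 3.2),
                             squeeze=False)
    for ax, key in zip(axes[0], keys):
        df = tables[key]
        ax.plot(df["threshold"], df["tp"], label="Tp", color="#2a7e43")
        ax.plot(df["threshold"], df["fp"], label="Fp", color="#b03a2e")
        ax.plot(df["threshold"], df["fn"], label="Fn", color="#7d3c98")
        ax.axhline(totals.get(key, 0), linestyle="--", color="k", lw=0.8)
        ax.set_title(key)
        ax.set_xlabel("Detection threshold")
        ax.set_ylabel("Count")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
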