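"""Metrics for both tasks.

Classification: per-criterion frame accuracy at a 0.5 probability threshold,
and precision/recall/F1 for milestone *achievement*, where a frame is
achieved iff all three criteria are met (an "any criterion" mode is
available).  Segmentation: per-class intersection-over-union and Dice with
pixel counts pooled over the whole evaluation set (micro aggregation;
per-image macro behind a flag), background excluded from the mean IOU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import AnatomyOntology
from .exceptions import ConfigError, DataError


@dataclass
class EvalReport:
    acc_c1: float
    acc_c2: float
    acc_c3: float
    precision: float
    recall: float
    f1: float
    per_class_iou: dict[str, float]
    miou: float
    dice: float
    support: dict[str, int] = field(default_factory=dict)
    zero_division: bool = False

    def to_dict(self) -> dict:
        return {
            "acc_c1": self.acc_c1, "acc_c2": self.acc_c2, "acc_c3": self.acc_c3,
            "achievement": {"precision": self.precision, "recall": self.recall,
                            "f1": self.f1},
            "per_class_iou": self.per_class_iou,
            "miou": self.miou, "dice": self.dice,
            "support": self.support, "zero_division": self.zero_division,
        }


def criterion_accuracy(probs: np.ndarray, labels: np.ndarray,
                       threshold: float = 0.5) -> tuple[float, float, float]:
    """Fraction of frames where (prob >= threshold) equals the label,
    per criterion."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if probs.ndim != 2 or probs.shape[1] != 3 or probs.shape != labels.shape:
        raise ConfigError(f"expected (N, 3) probs and labels, got {probs.shape}")
    if probs.shape[0] == 0:
        raise DataError("empty evaluation set")
    if probs.min() < 0 or probs.max() > 1:
        raise ConfigError("probabilities must lie in [0, 1]")
    pred = probs >= threshold
    acc = (pred == labels).mean(axis=0)
    return float(acc[0]), float(acc[1]), float(acc[2])


def achievement_prf(probs: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5, mode: str = "all"
                    ) -> tuple[float, float, float, bool]:
    """Precision/recall/F1 of milestone achievement.

    ``mode="all"``: achieved iff all three criteria positive (the clinical
    definition); ``mode="any"``: at least one.  Returns a zero-division flag
    set when a denominator was empty (the affected metric reports 0).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if probs.shape[0] == 0:
        raise DataError("empty evaluation set")
    if mode not in ("all", "any"):
        raise ConfigError(f"unknown achievement mode {mode!r}")
    agg = np.all if mode == "all" else np.any
    pred = agg(probs >= threshold, axis=1)
    true = agg(labels, axis=1)
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    flag = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return float(precision), float(recall), float(f1), flag


def segmentation_scores(pred_maps, true_maps, ontology: AnatomyOntology,
                        aggregation: str = "micro"):
    """Per-class IOU, mean IOU and Dice over anatomy classes.

    Background (class 0) is excluded.  ``micro`` pools pixel counts over the
    whole set; ``macro`` averages per-image scores.  A class with an empty
    union everywhere is excluded from the means.
    """
    pred_maps = [np.asarray(p) for p in pred_maps]
    true_maps = [np.asarray(t) for t in true_maps]
    if len(pred_maps) != len(true_maps) or not pred_maps:
        raise DataError("prediction/groundtruth map lists must match and be non-empty")
    for p, t in zip(pred_maps, true_maps):
        if p.shape != t.shape:
            raise ConfigError(f"map shape mismatch: {p.shape} vs {t.shape}")
    if aggregation not in ("micro", "macro"):
        raise ConfigError(f"unknown aggregation {aggregation!r}")

    classes = range(1, ontology.n_labels)
    per_class_iou: dict[str, float] = {}
    per_class_dice: dict[str, float] = {}
    for c in classes:
        name = ontology.label_name(c)
        if aggregation == "micro":
            inter = sum(int(np.sum((p == c) & (t == c)))
                        for p, t in zip(pred_maps, true_maps))
            psum = sum(int(np.sum(p == c)) for p in pred_maps)
            tsum = sum(int(np.sum(t == c)) for t in true_maps)
            union = psum + tsum - inter
            if union == 0:
                continue
            per_class_iou[name] = inter / union
            per_class_dice[name] = 2 * inter / (psum + tsum)
        else:
            ious, dices = [], []
            for p, t in zip(pred_maps, true_maps):
                inter = int(np.sum((p == c) & (t == c)))
                psum, tsum2 = int(np.sum(p == c)), int(np.sum(t == c))
                union = psum + tsum2 - inter
                if union == 0:
                    continue
                ious.append(inter / union)
                dices.append(2 * inter / (psum + tsum2))
            if not ious:
                continue
            per_class_iou[name] = float(np.mean(ious))
            per_class_dice[name] = float(np.mean(dices))

    if not per_class_iou:
        return {}, 0.0, 0.0
    miou = float(np.mean(list(per_class_iou.values())))
    dice = float(np.mean(list(per_class_dice.values())))
    return per_class_iou, miou, dice


def build_report(probs, labels, pred_maps, true_maps,
                 ontology: AnatomyOntology, threshold: float = 0.5,
                 mode: str = "all") -> EvalReport:
    a1, a2, a3 = criterion_accuracy(probs, labels, threshold)
    p, r, f1, flag = achievement_prf(probs, labels, threshold, mode)
    if pred_maps:
        per_class, miou, dice = segmentation_scores(pred_maps, true_maps, ontology)
    else:
        per_class, miou, dice = {}, 0.0, 0.0
    labels = np.asarray(labels).astype(bool)
    support = {
        "frames": int(len(labels)),
        "achieved_true": int(np.all(labels, axis=1).sum()),
        "masks": int(len(pred_maps)),
    }
    return EvalReport(a1, a2, a3, p, r, f1, per_class, miou, dice,
                      support, flag)
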