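"""Evaluation metrics and report assembly.

Implements the metrics reported throughout: per-class and macro average
precision (AP, the step-interpolated area under the precision-recall
curve), macro/micro F1, and for categorical tasks balanced accuracy
(mean per-class recall) and the multiclass Matthews correlation
coefficient.  Multi-label scores are thresholded at 0.5 for F1;
categorical predictions are taken by argmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import LabelSet


def average_precision(truth: np.ndarray, scores: np.ndarray) -> float:
    """Step AP: sum of precision * recall-increment over descending
    score thresholds; tied scores are treated as one group.

    Undefined (NaN) when the truth contains a single class.
    """
    truth = np.asarray(truth).astype(bool)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(truth.sum())
    if n_pos == 0 or n_pos == truth.size:
        return float("nan")
    order = np.argsort(-scores, kind="stable")
    s, t = scores[order], truth[order]
    # group boundaries: last index of each tied-score run
    boundary = np.nonzero(np.diff(s))[0]
    idx = np.concatenate([boundary, [s.size - 1]])
    tp = np.cumsum(t)[idx].astype(np.float64)
    fp = np.cumsum(~t)[idx].astype(np.float64)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return float(np.sum(np.diff(recall, prepend=0.0) * precision))


def _binary_f1(tp: float, fp: float, fn: float) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def f1_scores(truth: np.ndarray, pred: np.ndarray) -> dict:
    """Per-class, macro and micro F1 from aligned binary matrices (N, C)."""
    truth = np.atleast_2d(np.asarray(truth).astype(bool))
    pred = np.atleast_2d(np.asarray(pred).astype(bool))
    if truth.shape != pred.shape:
        raise ValueError("truth/pred shape mismatch")
    tp = (truth & pred).sum(axis=0).astype(float)
    fp = (~truth & pred).sum(axis=0).astype(float)
    fn = (truth & ~pred).sum(axis=0).astype(float)
    per_class = np.array([_binary_f1(*c) for c in zip(tp, fp, fn)])
    return {
        "per_class": per_class,
        "macro": float(per_class.mean()),
        "micro": float(_binary_f1(tp.sum(), fp.sum(), fn.sum())),
    }


def confusion_matrix(truth: np.ndarray, pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (np.asarray(truth, dtype=int), np.asarray(pred, dtype=int)), 1)
    return cm


def balanced_accuracy_mcc(truth: np.ndarray, pred: np.ndarray,
                          n_classes: int | None = None) -> tuple[float, float]:
    """Balanced accuracy (mean per-class recall) and multiclass MCC."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    k = n_classes or int(max(truth.max(), pred.max())) + 1
    cm = confusion_matrix(truth, pred, k)
    support = cm.sum(axis=1)
    recalls = np.divide(np.diag(cm), support, out=np.full(k, np.nan),
                        where=support > 0)
    ba = float(np.nanmean(recalls))
    t_k = cm.sum(axis=1).astype(float)   # truth counts
    p_k = cm.sum(axis=0).astype(float)   # prediction counts
    c = float(np.trace(cm))
    s = float(cm.sum())
    num = c * s - float(t_k @ p_k)
    den = np.sqrt(s * s - float(p_k @ p_k)) * np.sqrt(s * s - float(t_k @ t_k))
    mcc = num / den if den > 0 else 0.0
    return ba, float(mcc)


@dataclass
class EvalReport:
    label_set: str
    mode: str
    n_videos: int
    ap_per_class: dict[str, float]
    macro_ap: float
    f1_per_class: dict[str, float]
    macro_f1: float
    micro_f1: float
    balanced_accuracy: float | None = None
    mcc: float | None = None
    confusion: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "label_set": self.label_set, "mode": self.mode,
            "n_videos": self.n_videos,
            "ap_per_class": self.ap_per_class, "macro_ap": self.macro_ap,
            "f1_per_class": self.f1_per_class,
            "macro_f1": self.macro_f1, "micro_f1": self.micro_f1,
        }
        if self.balanced_accuracy is not None:
            d["balanced_accuracy"] = self.balanced_accuracy
            d["mcc"] = self.mcc
        if self.confusion is not None:
            d["confusion"] = self.confusion.tolist()
        d.update(self.extras)
        return d

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as f:
            json.dump(self.to_dict(), f, indent=2)
        pd.DataFrame({
            "label": list(self.ap_per_class),
            "ap": list(self.ap_per_class.values()),
            "f1": list(self.f1_per_class.values()),
        }).to_csv(out / "per_class.csv", index=False)


def summarize_folds(reports: list[EvalReport]) -> dict:
    """Mean +- sd over per-fold reports for every scalar metric."""
    if not reports:
        raise ValueError("no fold reports to summarize")
    out: dict = {"n_folds": len(reports)}
    scalars = ["macro_ap", "macro_f1", "micro_f1"]
    if reports[0].balanced_accuracy is not None:
        scalars += ["balanced_accuracy", "mcc"]
    for name in scalars:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        out[name] = {"mean": float(np.nanmean(vals)),
                     "sd": float(np.nanstd(vals, ddof=1)) if len(vals) > 1
                     else 0.0}
    return out


def evaluate(truth: np.ndarray, scores: np.ndarray, label_set: LabelSet,
             threshold: float = 0.5) -> EvalReport:
    """Score a (N, C) truth matrix against (N, C) soft scores.

    ``truth`` is binary per class (categorical truth one-hot encoded).
    """
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=np.float64)
    if truth.shape != scores.shape or truth.shape[1] != len(label_set):
        raise ValueError("truth/scores misaligned with the label set")
    n, c = truth.shape
    aps = {lab: average_precision(truth[:, j], scores[:, j])
           for j, lab in enumerate(label_set.labels)}
    macro_ap = float(np.nanmean(list(aps.values())))
    if label_set.mode == "categorical":
        t_id = truth.argmax(axis=1)
        p_id = scores.argmax(axis=1)
        pred = np.zeros_like(truth)
        pred[np.arange(n), p_id] = 1
        f1 = f1_scores(truth.astype(bool), pred.astype(bool))
        ba, mcc = balanced_accuracy_mcc(t_id, p_id, c)
        cm = confusion_matrix(t_id, p_id, c)
    else:
        pred = scores >= threshold
        f1 = f1_scores(truth.astype(bool), pred)
        ba = mcc = None
        cm = None
    return EvalReport(
        label_set=label_set.name, mode=label_set.mode, n_videos=n,
        ap_per_class=aps, macro_ap=macro_ap,
        f1_per_class=dict(zip(label_set.labels, f1["per_class"])),
        macro_f1=f1["macro"], micro_f1=f1["micro"],
        balanced_accuracy=ba, mcc=mcc, confusion=cm,
    )
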