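"""Reproducible desk-scale phantom experiments.

These functions run the full pipeline — phantom generation, masking and
standardization, clip training with polar augmentation, video-level
inference, and (for the semi-supervised variant) uncertainty-aware
pseudo-labeling — at sizes that complete in minutes on one CPU: 64 px
renders standardized to 32 px, 3-4 s videos at 25 fps, the tiny network
variant, and a binary normal-vs-pathological task.  They are the
package's own scaled-down study and back both the test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clips import ClipSpec
from .evaluation import balanced_accuracy_mcc, f1_scores
from .labels import NORMAL, build_default_hierarchy
from .network import NetworkSpec
from .phantom import PhantomConfig, generate_samples
from .preprocess import standardize
from .ssl import UPSThresholds, run_ssl_round
from .training import (SplitPlan, TrainConfig, TrainingRecord,
                       patient_level_split, predict_video, train_model)

_NORMAL_LEAVES = frozenset(build_default_hierarchy().leaves(NORMAL))

DESK_PHANTOM = dict(image_size=64, duration_range_s=(3.0, 4.0),
                    fps_choices=(25.0,))
DESK_CLIPS = ClipSpec(n_frames=16, rate_hz=8.0)
DESK_INPUT = (16, 32, 32)


def _binary_target(positives) -> np.ndarray:
    """(normal, pathological) one-hot from a finding list."""
    is_normal = bool(set(positives) & _NORMAL_LEAVES)
    return np.array([1.0, 0.0]) if is_normal else np.array([0.0, 1.0])


@dataclass
class BinaryDataset:
    labeled: list[TrainingRecord]
    unlabeled: list[tuple]               # (video, geometry)
    unlabeled_truth: list[np.ndarray]
    test: list[tuple]                    # (video, geometry, target)


def make_binary_dataset(seed: int, n_videos: int = 200,
                        labeled_fraction: float = 1.0,
                        size: int = 32,
                        test_fraction: float = 0.2) -> BinaryDataset:
    """Phantoms standardized to ``size`` with a patient-level split."""
    cfg = PhantomConfig(**DESK_PHANTOM)
    rng = np.random.default_rng(seed)
    samples = generate_samples(cfg, n_videos, labeled_fraction, rng)
    split = patient_level_split(
        pd.DataFrame({"patient_id": [s.patient_id for s in samples]}),
        SplitPlan(test_fraction=test_fraction, n_folds=2), seed=seed)
    ds = BinaryDataset([], [], [], [])
    for s, part in zip(samples, split["partition"]):
        std, g2 = standardize(s.video, s.geometry, size=size)
        y = _binary_target(s.labels.positives())
        if part == "test":
            ds.test.append((std, g2, y))
        elif s.labeled:
            ds.labeled.append(TrainingRecord(std, g2, y))
        else:
            ds.unlabeled.append((std, g2))
            ds.unlabeled_truth.append(y)
    return ds


def _macro_f1(model, test, mode: str) -> float:
    truth = np.array([y for _, _, y in test])
    scores = np.array([predict_video(model, v, DESK_CLIPS)
                       for v, _, _ in test])
    if mode == "categorical":
        pred = np.eye(truth.shape[1])[scores.argmax(axis=1)]
    else:
        pred = scores >= 0.5
    return f1_scores(truth > 0.5, pred)["macro"]


def supervised_binary_run(seed: int, n_videos: int = 200,
                          epochs: int = 20) -> dict:
    """Supervised normal-vs-pathological: train the tiny categorical
    network on labeled phantoms and score the held-out patients."""
    ds = make_binary_dataset(seed, n_videos, labeled_fraction=1.0)
    tc = TrainConfig(epochs=epochs, batch_size=4, lr=1e-3, smoothing=0.0,
                     mode="categorical", clip_spec=DESK_CLIPS, seed=seed)
    net = NetworkSpec.make_tiny(2, "softmax", input_shape=DESK_INPUT)
    model, history = train_model(ds.labeled, 2, tc, network=net)
    truth = [int(np.argmax(y)) for _, _, y in ds.test]
    pred = [int(np.argmax(predict_video(model, v, DESK_CLIPS)))
            for v, _, _ in ds.test]
    ba, mcc = balanced_accuracy_mcc(truth, pred, 2)
    return {"balanced_accuracy": ba, "mcc": mcc,
            "n_train": len(ds.labeled), "n_test": len(ds.test),
            "final_loss": float(history["loss"].iloc[-1])}


def ssl_binary_run(seed: int, n_videos: int = 200,
                   labeled_fraction: float = 0.25,
                   epochs: int = 20,
                   thresholds: UPSThresholds | None = None) -> dict:
    """One UPS round on mostly-unlabeled phantoms (multi-label binary
    task so per-class reliability bits are exercised).

    Reports the precision of selected pseudo-labels against the
    generator's truth, the naive 0.5-threshold precision over all
    class-entries as the unselected baseline, and held-out macro F1 of
    the supervised and semi-supervised models.
    """
    thresholds = thresholds or UPSThresholds()
    ds = make_binary_dataset(seed, n_videos, labeled_fraction)
    tc = TrainConfig(epochs=epochs, batch_size=4, lr=1e-3, smoothing=0.1,
                     mode="multi-label", clip_spec=DESK_CLIPS, seed=seed)
    net = NetworkSpec.make_tiny(2, "sigmoid", input_shape=DESK_INPUT)
    result = run_ssl_round(ds.labeled, ds.unlabeled, tc, thresholds,
                           network=net,
                           class_names=["normal", "pathological"])
    sel_ok = sel_n = all_ok = 0
    for rec, y in zip(result.records, ds.unlabeled_truth):
        for c in range(2):
            all_ok += float((rec.prediction[c] > 0.5) == (y[c] > 0.5))
            if rec.g[c]:
                sel_ok += float(rec.y[c] == y[c])
                sel_n += 1
    n_entries = 2 * len(ds.unlabeled)
    return {
        "selected_precision": sel_ok / max(1, sel_n),
        "baseline_precision": all_ok / max(1, n_entries),
        "n_selected_entries": sel_n,
        "n_selected_videos": result.n_selected_videos,
        "n_unlabeled": len(ds.unlabeled),
        "macro_f1_supervised": _macro_f1(result.supervised_model, ds.test,
                                         "multi-label"),
        "macro_f1_ssl": _macro_f1(result.model, ds.test, "multi-label"),
    }
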