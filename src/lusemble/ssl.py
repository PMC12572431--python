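"""Uncertainty-aware pseudo-labeling (UPS) and the semi-supervised round.

A trained supervised model scores every unlabeled video with the
video-level inference routine; the same video is additionally scored
under nine weakly-augmented versions (one shared augmentation draw per
version, applied to the whole video so every clip of a version sees the
same parameters).  The original version's score is the confidence p;
the per-class standard deviation over all ten scores is the uncertainty
u.  A class becomes a positive pseudo-label when p > tau_p and u < k_p,
a negative one when p < tau_n and u < k_n, and is otherwise
indeterminate (reliability bit g = 0, excluded from the loss).
Selected videos join the labeled set and the network is re-trained from
scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd

from .clips import ClipSpec
from .core import SectorGeometry, VideoClip
from .network import NetworkSpec, R2Plus1D
from .polar import AugmentationPolicy, apply_augmentation, draw_augmentation
from .training import TrainConfig, TrainingRecord, predict_video, train_model


@dataclass(frozen=True)
class UPSThresholds:
    """Confidence / uncertainty cutoffs (strict inequalities)."""

    tau_p: float = 0.5
    tau_n: float = 0.05
    k_p: float = 0.05
    k_n: float = 0.005

    def __post_init__(self) -> None:
        if self.tau_n > self.tau_p:
            raise ValueError("need tau_n <= tau_p")


POSITIVE, NEGATIVE, INDETERMINATE = "positive", "negative", "indeterminate"


@dataclass
class PseudoLabelRecord:
    prediction: np.ndarray        # p per class
    uncertainty: np.ndarray       # u per class
    assignment: list[str]         # per class in {positive, negative, indeterminate}
    y: np.ndarray                 # hard pseudo-labels (0 where not positive)
    g: np.ndarray                 # reliability bits


def predict_with_uncertainty(model: R2Plus1D, video: VideoClip,
                             geometry: SectorGeometry,
                             weak_policy: AugmentationPolicy,
                             clip_spec: ClipSpec,
                             rng: np.random.Generator,
                             n_aug: int = 9) -> tuple[np.ndarray, np.ndarray]:
    """(p, u) per class from the original + ``n_aug`` weak augmentations.

    All versions' clips are scored in one batched forward pass; the
    per-version video-level score is the mean over that version's clips.
    """
    from .clips import enumerate_clips

    version_clips: list[list[np.ndarray]] = []
    batch = enumerate_clips(video, clip_spec)
    version_clips.append([c.frames for c in batch.clips])
    for _ in range(n_aug):
        draw = draw_augmentation(weak_policy, rng)
        aug, _g = apply_augmentation(video, geometry, draw)
        batch = enumerate_clips(aug, clip_spec)
        version_clips.append([c.frames for c in batch.clips])
    flat = np.stack([f for clips in version_clips for f in clips])[:, None]
    scores = model.predict_proba(flat)
    versions, k = [], 0
    for clips in version_clips:
        versions.append(scores[k:k + len(clips)].mean(axis=0))
        k += len(clips)
    arr = np.stack(versions)
    p = arr[0]
    u = arr.std(axis=0)  # population standard deviation over the n_aug+1 scores
    return p, u


def select_pseudo_labels(p: np.ndarray, u: np.ndarray, th: UPSThresholds,
                         mode: str = "multi-label") -> PseudoLabelRecord:
    """Apply the UPS rule per class (or per sample in categorical mode).

    Categorical: the argmax class must qualify as positive, in which
    case the sample becomes a reliable one-hot label; otherwise the
    whole sample is rejected (g = 0 everywhere).
    """
    p = np.asarray(p, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    c = p.size
    y = np.zeros(c)
    g = np.zeros(c)
    assignment = [INDETERMINATE] * c
    if mode == "categorical":
        j = int(np.argmax(p))
        if p[j] > th.tau_p and u[j] < th.k_p:
            y[j] = 1.0
            g[:] = 1.0
            assignment = [NEGATIVE] * c
            assignment[j] = POSITIVE
        return PseudoLabelRecord(p, u, assignment, y, g)
    for j in range(c):
        if p[j] > th.tau_p and u[j] < th.k_p:
            y[j], g[j], assignment[j] = 1.0, 1.0, POSITIVE
        elif p[j] < th.tau_n and u[j] < th.k_n:
            y[j], g[j], assignment[j] = 0.0, 1.0, NEGATIVE
    return PseudoLabelRecord(p, u, assignment, y, g)


@dataclass
class SSLRoundResult:
    model: R2Plus1D
    supervised_model: R2Plus1D
    records: list[PseudoLabelRecord]
    report: pd.DataFrame          # video, class, p, u, assignment
    n_selected_videos: int
    history: pd.DataFrame


def run_ssl_round(labeled: list[TrainingRecord],
                  unlabeled: list[tuple[VideoClip, SectorGeometry]],
                  config: TrainConfig,
                  thresholds: UPSThresholds,
                  network: NetworkSpec | None = None,
                  weak_policy: AugmentationPolicy | None = None,
                  supervised_model: R2Plus1D | None = None,
                  n_aug: int = 9,
                  class_names: list[str] | None = None,
                  n_rounds: int = 1) -> SSLRoundResult:
    """One (or more) UPS rounds: train, pseudo-label, select, retrain.

    Each round regenerates pseudo-labels for *all* unlabeled videos with
    the current classifier and re-trains a fresh network from scratch on
    labeled + selected.  The default is a single round: repeated
    self-training amplifies confirmation bias in overconfident models.
    """
    weak_policy = weak_policy or AugmentationPolicy.weak()
    n_classes = labeled[0].target.size
    names = class_names or [f"class_{j}" for j in range(n_classes)]
    if supervised_model is None:
        supervised_model, _ = train_model(labeled, n_classes, config,
                                          network=network)
    if not unlabeled:
        warnings.warn("no unlabeled videos: degenerate round, plain "
                      "supervised retrain", stacklevel=2)

    current = supervised_model
    records: list[PseudoLabelRecord] = []
    history = pd.DataFrame()
    for rnd in range(n_rounds):
        rng = np.random.default_rng(config.seed + 1000 + rnd)
        records = []
        selected: list[TrainingRecord] = []
        for video, geom in unlabeled:
            p, u = predict_with_uncertainty(current, video, geom, weak_policy,
                                            config.clip_spec, rng, n_aug=n_aug)
            rec = select_pseudo_labels(p, u, thresholds, mode=config.mode)
            records.append(rec)
            if rec.g.sum() > 0:
                selected.append(TrainingRecord(video, geom, rec.y, rec.g))
        retrain_seed = config.seed + 10 * rnd  # round 0 mirrors the supervised run
        current, history = train_model(
            labeled + selected, n_classes,
            replace(config, seed=retrain_seed), network=network)

    rows = []
    for i, rec in enumerate(records):
        for j, name in enumerate(names):
            rows.append({"video": i, "class": name,
                         "p": rec.prediction[j], "u": rec.uncertainty[j],
                         "assignment": rec.assignment[j]})
    report = pd.DataFrame(rows, columns=["video", "class", "p", "u", "assignment"])
    n_sel = sum(1 for r in records if r.g.sum() > 0)
    return SSLRoundResult(model=current, supervised_model=supervised_model,
                          records=records, report=report,
                          n_selected_videos=n_sel, history=history)
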