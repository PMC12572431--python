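"""Supervised training: label smoothing, reliability-masked losses,
patient-level splitting and the fit loop.

The masked losses implement the reliability-weighted cross-entropies
used for pseudo-labeled data: each class c of each sample carries a bit
g_c; only reliable classes enter the per-sample average, and a sample
whose bits are all zero is dropped from the batch mean (the
normalization is undefined there, and upstream selection discards such
samples anyway).  For labeled samples g is identically 1 and the losses
reduce to the standard (binary/categorical) cross-entropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clips import ClipSpec, aggregate_clip_scores, enumerate_clips, extract_clip
from .core import SectorGeometry, VideoClip
from .network import Adam, NetworkSpec, R2Plus1D
from .polar import AugmentationPolicy, augment_clip


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 4
    lr: float = 1e-3
    smoothing: float = 0.1          # LSR factor; 0 for categorical runs
    seed: int = 0
    clip_spec: ClipSpec = field(default_factory=ClipSpec)
    augment: AugmentationPolicy = field(default_factory=AugmentationPolicy.train)
    mode: str = "multi-label"       # "categorical" | "multi-label"

    def __post_init__(self) -> None:
        if not 0 <= self.smoothing < 1:
            raise ValueError("smoothing factor must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class TrainingRecord:
    """One preprocessed video ready for the fit loop."""

    video: VideoClip
    geometry: SectorGeometry
    target: np.ndarray              # hard or pseudo label vector, length C
    g: np.ndarray | None = None     # reliability bits; None = all ones

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=np.float64)
        if self.g is None:
            self.g = np.ones_like(self.target)
        else:
            self.g = np.asarray(self.g, dtype=np.float64)


# ---------------------------------------------------------------------------
# losses and smoothing

def smooth_labels(y: np.ndarray, eps: float, mode: str) -> np.ndarray:
    """Label smoothing: categorical y(1-eps) + eps/C, per-class binary
    y(1-eps) + eps/2."""
    y = np.asarray(y, dtype=np.float64)
    if eps == 0:
        return y.copy()
    if mode == "categorical":
        c = y.shape[-1]
        return y * (1 - eps) + eps / c
    return y * (1 - eps) + eps / 2


def masked_bce_loss(y: np.ndarray, y_hat: np.ndarray, g: np.ndarray) -> float:
    """Reliability-masked binary cross-entropy, averaged over samples
    with at least one reliable class."""
    y, y_hat, g = (np.atleast_2d(np.asarray(a, dtype=np.float64))
                   for a in (y, y_hat, g))
    if not (y.shape == y_hat.shape == g.shape):
        raise ValueError("y, y_hat and g must be aligned")
    per_class = -(y * np.log(y_hat) + (1 - y) * np.log(1 - y_hat))
    gsum = g.sum(axis=1)
    valid = gsum > 0
    if not valid.any():
        raise ValueError("no sample has a reliable class")
    per_sample = (g * per_class).sum(axis=1)[valid] / gsum[valid]
    return float(per_sample.mean())


def masked_cce_loss(y: np.ndarray, y_hat: np.ndarray, g: np.ndarray) -> float:
    """Reliability-masked categorical cross-entropy (g uniform per sample)."""
    y, y_hat, g = (np.atleast_2d(np.asarray(a, dtype=np.float64))
                   for a in (y, y_hat, g))
    if not (y.shape == y_hat.shape == g.shape):
        raise ValueError("y, y_hat and g must be aligned")
    valid = g.sum(axis=1) > 0
    if not valid.any():
        raise ValueError("no sample has a reliable class")
    per_sample = -(g * y * np.log(y_hat)).sum(axis=1)[valid]
    return float(per_sample.mean())


def _loss_and_dlogits(logits: np.ndarray, y: np.ndarray, g: np.ndarray,
                      mode: str) -> tuple[float, np.ndarray]:
    """Numerically-stable loss + gradient at the logits."""
    valid = g.sum(axis=1) > 0
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0, np.zeros_like(logits)
    if mode == "categorical":
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        per_sample = -(y * logp).sum(axis=1)
        loss = float(per_sample[valid].mean())
        d = (np.exp(logp) - y) / n_valid
        d[~valid] = 0.0
        return loss, d
    p = 1.0 / (1.0 + np.exp(-logits))
    per_class = np.logaddexp(0.0, logits) - y * logits
    gsum = np.where(valid, g.sum(axis=1), 1.0)
    per_sample = (g * per_class).sum(axis=1) / gsum
    loss = float(per_sample[valid].mean())
    d = g * (p - y) / gsum[:, None] / n_valid
    d[~valid] = 0.0
    return loss, d


def cosine_lr(epoch: int, total_epochs: int, lr0: float) -> float:
    """Cosine decay from lr0 (epoch 0) to 0 (final epoch)."""
    if total_epochs <= 1:
        return lr0
    return lr0 * 0.5 * (1 + math.cos(math.pi * epoch / (total_epochs - 1)))


# ---------------------------------------------------------------------------
# patient-level splitting

@dataclass(frozen=True)
class SplitPlan:
    test_fraction: float = 0.2
    n_folds: int = 5


def patient_level_split(manifest: pd.DataFrame, plan: SplitPlan,
                        seed: int) -> pd.DataFrame:
    """Assign each patient to train/test and each train patient to a CV fold.

    Returns a frame indexed like ``manifest`` with columns ``partition``
    ("train"/"test") and ``fold`` (0..k-1 for train rows, -1 for test).
    All videos of a patient share a partition and fold.
    """
    patients = manifest["patient_id"].unique()
    if len(patients) < plan.n_folds:
        raise ValueError("fewer patients than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_test = int(round(plan.test_fraction * len(patients)))
    test_patients = set(patients[order[:n_test]])
    train_patients = [patients[i] for i in order[n_test:]]
    fold_of = {p: i % plan.n_folds for i, p in enumerate(train_patients)}
    partition = ["test" if p in test_patients else "train"
                 for p in manifest["patient_id"]]
    fold = [fold_of.get(p, -1) for p in manifest["patient_id"]]
    return pd.DataFrame({"partition": partition, "fold": fold},
                        index=manifest.index)


# ---------------------------------------------------------------------------
# fit loop and video-level inference

def predict_video(model: R2Plus1D, video: VideoClip, spec: ClipSpec) -> np.ndarray:
    """Video-level scores: enumerate overlapping clips, average their scores."""
    batch = enumerate_clips(video, spec)
    x = np.stack([c.frames for c in batch.clips])[:, None]
    scores = model.predict_proba(x)
    return aggregate_clip_scores(list(scores))


def fit_supervised(model: R2Plus1D, records: list[TrainingRecord],
                   config: TrainConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Train in place; returns the per-epoch history (epoch, lr, loss).

    Each epoch visits every video once in a shuffled order, draws one
    uniformly random clip per video, augments it with per-clip
    parameters and optimizes the smoothed, reliability-masked loss.
    """
    if not records:
        raise ValueError("empty training set")
    rng = rng or np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.lr)
    span = config.clip_spec.span_s
    history = []
    for epoch in range(config.epochs):
        opt.lr = cosine_lr(epoch, config.epochs, config.lr)
        order = rng.permutation(len(records))
        losses = []
        for i0 in range(0, len(order), config.batch_size):
            idx = order[i0:i0 + config.batch_size]
            xs, ys, gs = [], [], []
            for j in idx:
                rec = records[j]
                start = rng.uniform(0, max(0.0, rec.video.duration_s - span))
                clip = extract_clip(rec.video, start, config.clip_spec)
                clip = augment_clip(clip, rec.geometry, config.augment, rng)
                xs.append(clip.frames)
                ys.append(smooth_labels(rec.target, config.smoothing, config.mode))
                gs.append(rec.g)
            x = np.stack(xs)[:, None]
            y = np.stack(ys)
            g = np.stack(gs)
            model.zero_grad()
            logits = model.forward(x, train=True)
            loss, dlogits = _loss_and_dlogits(logits, y, g, config.mode)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss}")
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append({"epoch": epoch, "lr": opt.lr,
                        "loss": float(np.mean(losses))})
    return pd.DataFrame(history)


def cross_validate(records: list[TrainingRecord], folds: list[int],
                   label_set, config: TrainConfig,
                   network: NetworkSpec | None = None) -> tuple[list, dict]:
    """k-fold cross-validation over pre-assigned (patient-level) folds.

    Trains one fresh model per fold on the out-of-fold records and
    scores the held-in fold with video-level inference; returns the
    per-fold reports and their mean +- sd summary.
    """
    from .evaluation import evaluate, summarize_folds

    folds = list(folds)
    if len(folds) != len(records):
        raise ValueError("one fold id per record required")
    reports = []
    for k in sorted(set(folds)):
        train = [r for r, f in zip(records, folds) if f != k]
        held = [r for r, f in zip(records, folds) if f == k]
        if not train or not held:
            raise ValueError(f"fold {k} leaves an empty partition")
        model, _ = train_model(train, len(label_set), config,
                               network=network, seed=config.seed + k)
        truth = np.array([r.target for r in held])
        scores = np.array([predict_video(model, r.video, config.clip_spec)
                           for r in held])
        reports.append(evaluate(truth, scores, label_set))
    return reports, summarize_folds(reports)


def train_model(records: list[TrainingRecord], n_outputs: int,
                config: TrainConfig, network: NetworkSpec | None = None,
                seed: int | None = None) -> tuple[R2Plus1D, pd.DataFrame]:
    """Build a fresh network and fit it; convenience wrapper."""
    seed = config.seed if seed is None else seed
    head = "softmax" if config.mode == "categorical" else "sigmoid"
    spec = network or NetworkSpec.default(n_outputs, head)
    model = R2Plus1D(spec, seed=seed)
    history = fit_supervised(model, records, config,
                             rng=np.random.default_rng(seed))
    return model, history
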