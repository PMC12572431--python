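"""End-to-end orchestration: generate, preprocess, train, ssl, ensemble, evaluate.

Each stage reads the resolved run configuration (one YAML per run,
archived in the run directory), writes its outputs plus a small
``<stage>.done.json`` marker holding a hash of the configuration keys
it depends on, and is skipped on re-runs while that hash matches.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clips import ClipSpec
from .core import SectorGeometry, VideoClip
from .ensemble import EnsembleMember, EnsembleSpec, ensemble_predict
from .evaluation import evaluate
from .labels import LabelSet, LabelVector, low_to_high_map, resolve_label_set
from .network import NetworkSpec, R2Plus1D
from .phantom import MLS4, PhantomConfig, generate_dataset, load_video
from .polar import AugmentationPolicy
from .preprocess import apply_fov_mask, estimate_sector_geometry, standardize
from .ssl import UPSThresholds, run_ssl_round
from .training import (SplitPlan, TrainConfig, TrainingRecord,
                       patient_level_split, predict_video, train_model)

log = logging.getLogger("lusemble")

STAGES = ("generate", "preprocess", "train", "ssl", "ensemble", "evaluate")

# configuration keys each stage depends on (for resume hashing)
_STAGE_KEYS = {
    "generate": ("seed", "phantom"),
    "preprocess": ("seed", "phantom", "preprocess"),
    "train": ("seed", "phantom", "preprocess", "label_set", "clip", "network",
              "train", "augment", "split"),
    "ssl": ("seed", "phantom", "preprocess", "label_set", "clip", "network",
            "train", "augment", "split", "ups"),
    "ensemble": ("seed", "phantom", "preprocess", "label_set", "clip",
                 "network", "train", "augment", "split", "ups", "ensemble"),
    "evaluate": ("seed", "phantom", "preprocess", "label_set", "clip",
                 "network", "train", "augment", "split", "ups", "ensemble"),
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "label_set": "mlS4",
    "phantom": {"n_videos": 60, "labeled_fraction": 0.5, "image_size": 64,
                "duration_range_s": [3.0, 4.0], "fps_choices": [25.0]},
    "preprocess": {"size": 32, "use_manifest_geometry": True},
    "clip": {"n_frames": 16, "rate_hz": 8.0, "step_s": 0.5},
    "network": {"tiny": True},
    "train": {"epochs": 3, "batch_size": 4, "lr": 1e-3, "smoothing": 0.1},
    "augment": {"scale_pct": 0.30, "rot_deg": 10.0, "contrast_gain": 0.25,
                "p_spatial": 0.5, "p_intensity": 0.15, "p_flip": 0.5},
    "ups": {"tau_p": 0.5, "tau_n": 0.05, "k_p": 0.05, "k_n": 0.005},
    "ensemble": {"k": 2},
    "split": {"test_fraction": 0.2, "n_folds": 5},
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _stage_hash(cfg: dict, stage: str) -> str:
    sub = {k: cfg.get(k) for k in _STAGE_KEYS[stage]}
    return hashlib.sha256(json.dumps(sub, sort_keys=True).encode()).hexdigest()[:16]


def _done(out: Path, stage: str) -> Path:
    return out / f"{stage}.done.json"


def _is_done(out: Path, cfg: dict, stage: str) -> bool:
    marker = _done(out, stage)
    if not marker.exists():
        return False
    with open(marker) as f:
        return json.load(f).get("hash") == _stage_hash(cfg, stage)


def _mark_done(out: Path, cfg: dict, stage: str, info: dict | None = None) -> None:
    payload = {"hash": _stage_hash(cfg, stage), "time": time.time()}
    payload.update(info or {})
    with open(_done(out, stage), "w") as f:
        json.dump(payload, f, indent=2)


def project_labels(truth: np.ndarray, target: LabelSet) -> tuple[np.ndarray, bool]:
    """Project an mlS4 truth vector onto a target label set.

    A target label is positive when any of its findings is.  For
    categorical sets the projection is usable only when exactly one
    target label fires (videos mixing categories are skipped, keeping
    the labels mutually exclusive).
    """
    mapping = low_to_high_map(MLS4, target)
    out = np.array([max(truth[MLS4.index(s)] for s in mapping[t])
                    for t in target.labels], dtype=np.float64)
    ok = True
    if target.mode == "categorical":
        ok = int(out.sum()) == 1
    return out, ok


# ---------------------------------------------------------------------------
# stage implementations

def _phantom_config(cfg: dict) -> PhantomConfig:
    p = dict(cfg["phantom"])
    p.pop("n_videos", None)
    p.pop("labeled_fraction", None)
    for key in ("duration_range_s", "fps_choices"):
        if key in p:
            p[key] = tuple(p[key])
    return PhantomConfig(**p)


def stage_generate(cfg: dict, out: Path) -> pd.DataFrame:
    data_dir = out / "data"
    rng = np.random.default_rng(cfg["seed"])
    manifest = generate_dataset(_phantom_config(cfg),
                                cfg["phantom"]["n_videos"],
                                cfg["phantom"]["labeled_fraction"],
                                rng, data_dir)
    log.info("generate: %d videos -> %s", len(manifest), data_dir)
    return manifest


def stage_preprocess(cfg: dict, out: Path) -> pd.DataFrame:
    data_dir = out / "data"
    proc_dir = out / "processed"
    proc_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    size = cfg["preprocess"]["size"]
    rows = []
    for _, row in manifest.iterrows():
        video = load_video(data_dir, row["path"])
        if cfg["preprocess"].get("use_manifest_geometry", True):
            g = SectorGeometry.from_dict(row)
        else:
            g = estimate_sector_geometry(video)
        std, g2 = standardize(apply_fov_mask(video, g), g, size=size)
        rel = Path(row["path"]).stem + "_proc.npz"
        np.savez_compressed(proc_dir / rel, frames=std.frames,
                            fps=np.float64(std.fps))
        with open(proc_dir / (Path(row["path"]).stem + "_geom.json"), "w") as f:
            json.dump(g2.to_dict(), f)
        new = dict(row)
        new["path"] = rel
        new.update(g2.to_dict())
        rows.append(new)
    proc = pd.DataFrame(rows)
    proc.to_csv(proc_dir / "manifest.csv", index=False)
    log.info("preprocess: %d videos -> %s", len(proc), proc_dir)
    return proc


def _load_records(cfg: dict, out: Path) -> tuple[list, list, list, LabelSet]:
    """(labeled train records, unlabeled (video, geom), test rows, label set)."""
    proc_dir = out / "processed"
    manifest = pd.read_csv(proc_dir / "manifest.csv")
    label_set = resolve_label_set(cfg["label_set"])
    split = patient_level_split(manifest, SplitPlan(
        cfg["split"]["test_fraction"], cfg["split"]["n_folds"]), cfg["seed"])
    labeled, unlabeled, test = [], [], []
    for (_, row), part in zip(manifest.iterrows(), split["partition"]):
        video = load_video(proc_dir, row["path"])
        geom = SectorGeometry.from_dict(row)
        has_labels = row["split"] == "labeled" and not pd.isna(row[MLS4.labels[0]])
        truth = (np.array([float(row[l]) for l in MLS4.labels])
                 if has_labels else None)
        if part == "test":
            if truth is not None:
                test.append((video, geom, truth))
            continue
        if truth is None:
            unlabeled.append((video, geom))
        else:
            target, ok = project_labels(truth, label_set)
            if ok:
                labeled.append(TrainingRecord(video, geom, target))
    return labeled, unlabeled, test, label_set


def _train_config(cfg: dict, label_set: LabelSet) -> TrainConfig:
    return TrainConfig(
        epochs=cfg["train"]["epochs"], batch_size=cfg["train"]["batch_size"],
        lr=cfg["train"]["lr"],
        smoothing=(cfg["train"]["smoothing"]
                   if label_set.mode == "multi-label" else 0.0),
        seed=cfg["seed"],
        clip_spec=ClipSpec(n_frames=cfg["clip"]["n_frames"],
                           rate_hz=cfg["clip"]["rate_hz"],
                           step_s=cfg["clip"]["step_s"]),
        augment=AugmentationPolicy(**cfg["augment"]),
        mode=label_set.mode)


def _network_spec(cfg: dict, label_set: LabelSet) -> NetworkSpec:
    head = "softmax" if label_set.mode == "categorical" else "sigmoid"
    size = cfg["preprocess"]["size"]
    shape = (cfg["clip"]["n_frames"], size, size)
    if cfg["network"].get("tiny", False):
        return NetworkSpec.make_tiny(len(label_set), head, input_shape=shape)
    return NetworkSpec(input_shape=shape, head=head, n_outputs=len(label_set))


def stage_train(cfg: dict, out: Path) -> R2Plus1D:
    labeled, _, _, label_set = _load_records(cfg, out)
    tc = _train_config(cfg, label_set)
    model, history = train_model(labeled, len(label_set), tc,
                                 network=_network_spec(cfg, label_set))
    run_dir = out / "train"
    run_dir.mkdir(exist_ok=True)
    model.save(run_dir / "model.npz", label_set.name)
    history.to_csv(run_dir / "history.csv", index=False)
    log.info("train: %d labeled videos, final loss %.4f",
             len(labeled), history["loss"].iloc[-1])
    return model


def stage_ssl(cfg: dict, out: Path) -> R2Plus1D:
    labeled, unlabeled, _, label_set = _load_records(cfg, out)
    tc = _train_config(cfg, label_set)
    sup_path = out / "train" / "model.npz"
    sup = R2Plus1D.load(sup_path)[0] if sup_path.exists() else None
    result = run_ssl_round(labeled, unlabeled, tc,
                           UPSThresholds(**cfg["ups"]),
                           network=_network_spec(cfg, label_set),
                           supervised_model=sup,
                           class_names=list(label_set.labels))
    run_dir = out / "ssl"
    run_dir.mkdir(exist_ok=True)
    result.model.save(run_dir / "model.npz", label_set.name)
    result.report.to_csv(run_dir / "pseudo_labels.csv", index=False)
    log.info("ssl: %d/%d unlabeled videos selected",
             result.n_selected_videos, len(unlabeled))
    return result.model


def stage_ensemble(cfg: dict, out: Path) -> EnsembleSpec:
    labeled, _, _, label_set = _load_records(cfg, out)
    tc = _train_config(cfg, label_set)
    from .ensemble import build_repetition_ensemble
    spec = build_repetition_ensemble(labeled, label_set, tc,
                                     k=cfg["ensemble"]["k"],
                                     network=_network_spec(cfg, label_set))
    run_dir = out / "ensemble"
    run_dir.mkdir(exist_ok=True)
    for i, m in enumerate(spec.members):
        m.model.save(run_dir / f"member_{i}.npz", label_set.name)
    return spec


def stage_evaluate(cfg: dict, out: Path) -> dict:
    _, _, test, label_set = _load_records(cfg, out)
    if not test:
        raise RuntimeError("no labeled test videos to evaluate")
    clip_spec = ClipSpec(n_frames=cfg["clip"]["n_frames"],
                         rate_hz=cfg["clip"]["rate_hz"],
                         step_s=cfg["clip"]["step_s"])
    reports = {}
    for name in ("train", "ssl"):
        ckpt = out / name / "model.npz"
        if not ckpt.exists():
            continue
        model, _ = R2Plus1D.load(ckpt)
        truth, scores = [], []
        for video, geom, t7 in test:
            target, ok = project_labels(t7, label_set)
            if not ok:
                continue
            truth.append(target)
            scores.append(predict_video(model, video, clip_spec))
        rep = evaluate(np.array(truth), np.array(scores), label_set)
        rep.save(out / "evaluate" / name)
        reports[name] = rep.to_dict()
        log.info("evaluate[%s]: macro F1 %.3f", name, rep.macro_f1)
    with open(out / "evaluate" / "summary.json", "w") as f:
        json.dump(reports, f, indent=2)
    return reports


_STAGE_FN = {
    "generate": stage_generate,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "ssl": stage_ssl,
    "ensemble": stage_ensemble,
    "evaluate": stage_evaluate,
}

_STAGE_DEPS = {
    "generate": (),
    "preprocess": ("generate",),
    "train": ("preprocess",),
    "ssl": ("train",),
    "ensemble": ("preprocess",),
    "evaluate": ("train",),
}


def run_pipeline(cfg: dict, out_dir: str | Path,
                 stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages in canonical order, resuming where
    a stage's configuration hash is unchanged."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False, allow_unicode=True)
    for stage in STAGES:
        if stage not in stages:
            continue
        for dep in _STAGE_DEPS[stage]:
            if not _is_done(out, cfg, dep):
                raise RuntimeError(
                    f"stage {stage!r} needs {dep!r}: run it first or add it "
                    f"(missing/outdated marker {_done(out, dep)})")
        if _is_done(out, cfg, stage):
            log.info("%s: up to date, skipped", stage)
            continue
        t0 = time.time()
        _STAGE_FN[stage](cfg, out)
        _mark_done(out, cfg, stage, {"seconds": round(time.time() - t0, 2)})
    return out
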