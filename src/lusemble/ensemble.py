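"""Hierarchy-aware model ensembling.

Members trained on different label sets are combined into a prediction
over a target set.  A member's scores are first lifted to the target
set: a target label present verbatim in the member is copied, otherwise
it is aggregated from the member labels beneath it — by summation for
categorical outputs (softmax mass is additive over disjoint
sub-labels) and by maximum for multi-label outputs (a high-level
finding is present when its most confident sub-finding is).  The
ensemble output is the unweighted mean of the lifted member scores.

When all members share the target label set this reduces to classical
model repetition; training the low-level (7-finding) model several
times and lifting is the low-to-high variant; mixing members across
the whole frontier is the multi-output-to-high-level strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .clips import ClipSpec
from .core import SectorGeometry, VideoClip
from .labels import LabelHierarchy, LabelSet, low_to_high_map
from .network import NetworkSpec, R2Plus1D
from .training import TrainConfig, TrainingRecord, predict_video, train_model


@dataclass
class EnsembleMember:
    label_set: LabelSet
    model: R2Plus1D | None = None
    score_table: dict[int, np.ndarray] | None = None  # video id -> scores

    def scores_for(self, key: int, video: VideoClip | None,
                   clip_spec: ClipSpec) -> np.ndarray:
        if self.score_table is not None and key in self.score_table:
            return np.asarray(self.score_table[key], dtype=np.float64)
        if self.model is None or video is None:
            raise ValueError("member has neither stored scores nor a model")
        return predict_video(self.model, video, clip_spec)


@dataclass
class EnsembleSpec:
    members: list[EnsembleMember]
    target: LabelSet
    mode: str                      # "categorical" | "multi-label"
    strategy: str = "multi-output-to-high-level"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an ensemble needs at least one member")
        if self.strategy == "model-repetition":
            for m in self.members:
                if m.label_set.labels != self.target.labels:
                    raise ValueError("model-repetition members must share "
                                     "the target label set")


def aggregate_member(scores: np.ndarray, member_set: LabelSet,
                     target: LabelSet, mode: str,
                     hierarchy: LabelHierarchy | None = None) -> np.ndarray:
    """Lift one member's scores onto the target label set."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (len(member_set),):
        raise ValueError("scores misaligned with the member label set")
    mapping = low_to_high_map(member_set, target, hierarchy)
    out = np.empty(len(target))
    for i, t in enumerate(target.labels):
        vals = np.array([scores[member_set.index(s)] for s in mapping[t]])
        if len(vals) == 1:
            out[i] = vals[0]
        elif mode == "categorical":
            out[i] = vals.sum()
        else:
            out[i] = vals.max()
    return out


def ensemble_predict(spec: EnsembleSpec, video: VideoClip | None = None,
                     key: int = 0,
                     clip_spec: ClipSpec | None = None) -> np.ndarray:
    """Mean over members of their scores lifted to the target set."""
    clip_spec = clip_spec or ClipSpec()
    lifted = [aggregate_member(m.scores_for(key, video, clip_spec),
                               m.label_set, spec.target, spec.mode)
              for m in spec.members]
    return np.mean(lifted, axis=0)


def build_repetition_ensemble(records: list[TrainingRecord], label_set: LabelSet,
                              config: TrainConfig, k: int = 4,
                              network: NetworkSpec | None = None) -> EnsembleSpec:
    """Train ``k`` independently-seeded copies of the same model."""
    if k < 2:
        import warnings
        warnings.warn("k < 2 gives a degenerate single-model ensemble",
                      stacklevel=2)
    members = []
    for i in range(max(1, k)):
        model, _ = train_model(records, len(label_set),
                               replace(config, seed=config.seed + 101 * i),
                               network=network)
        members.append(EnsembleMember(label_set=label_set, model=model))
    return EnsembleSpec(members=members, target=label_set, mode=label_set.mode,
                        strategy="model-repetition")
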