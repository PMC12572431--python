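"""Fixed-length clip extraction and video-level score aggregation.

The classifier consumes 32-frame clips sampled at 8 Hz, i.e. a 4 s
window covering a full respiratory cycle.  At inference time a video is
divided into overlapping clips starting every 0.5 s from the first
frame, and the per-clip class scores are averaged into a video-level
prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import VideoClip


@dataclass(frozen=True)
class ClipSpec:
    n_frames: int = 32
    rate_hz: float = 8.0
    step_s: float = 0.5
    pad_value: float = 0.0
    include_partial: bool = False  # enumerate trailing clips that pad past the end

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.rate_hz <= 0 or self.step_s <= 0:
            raise ValueError("need n_frames >= 1, rate_hz > 0, step_s > 0")

    @property
    def span_s(self) -> float:
        return self.n_frames / self.rate_hz


@dataclass
class ClipBatch:
    clips: list[VideoClip]
    start_times: list[float]

    def __len__(self) -> int:
        return len(self.clips)


def extract_clip(video: VideoClip, start_s: float, spec: ClipSpec) -> VideoClip:
    """Resample ``spec.n_frames`` frames at ``spec.rate_hz`` from ``start_s``.

    Frame i of the clip is the source frame nearest to time
    ``start_s + i/rate``; times past the end of the video yield
    pad-value frames appended at the clip's end.
    """
    if start_s < 0:
        raise ValueError("start must be >= 0")
    t_src = video.n_frames
    times = start_s + np.arange(spec.n_frames) / spec.rate_hz
    idx = np.round(times * video.fps).astype(int)
    real = idx < t_src
    if not real.any():
        warnings.warn("clip starts beyond the end of the video; all-pad clip",
                      stacklevel=2)
    h, w = video.frames.shape[1:]
    out = np.full((spec.n_frames, h, w), spec.pad_value, dtype=video.frames.dtype)
    out[real] = video.frames[idx[real]]
    return VideoClip(out, spec.rate_hz)


def enumerate_clips(video: VideoClip, spec: ClipSpec) -> ClipBatch:
    """Overlapping clip starts 0, step, 2*step, ...; always at least one clip.

    By default only starts whose full span lies inside the video are
    enumerated (clip statistics stay homogeneous); the guaranteed first
    clip pads when the whole video is shorter than the span.
    """
    duration = video.duration_s
    eps = 1e-9
    starts = [0.0]
    k = 1
    while True:
        s = k * spec.step_s
        if s >= duration - eps:
            break
        end_ok = (s + spec.span_s <= duration + eps) or spec.include_partial
        if end_ok:
            starts.append(s)
        elif not spec.include_partial:
            break
        k += 1
    if not spec.include_partial and spec.span_s > duration + eps:
        starts = [0.0]
    return ClipBatch([extract_clip(video, s, spec) for s in starts], starts)


def aggregate_clip_scores(scores: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Arithmetic mean of per-clip class-score vectors."""
    arr = np.asarray(scores, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty list of clip scores")
    if arr.ndim != 2:
        raise ValueError("scores must be a list of equal-length vectors")
    return arr.mean(axis=0)
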