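"""Synthetic sector-scan lung-ultrasound phantoms.

Generates labeled grayscale videos with the geometry and artifact
topology of convex-probe lung POCUS: multiplicative speckle, a bright
pleural arc, equally-spaced A-line reverberation arcs, radial B-line
rays that rock with breathing (and may be transient), coalescent
B-line bands, hypoechoic consolidation patches and anechoic pleural
effusion bands.  Intensity models are deliberately ad hoc — the point
is a dataset whose labels are learnable from geometry/artifact
structure, not acoustic realism.

Findings are drawn under the co-occurrence rules of the label
hierarchy: a video is normal (exactly one of scattering-only /
A-lines) or pathological (at most one B-line finding, plus
independently sampled consolidation / pleural effusion, never empty).

The generator additionally records per-video rendering ground truth
(ray angles, per-frame B-line presence) for diagnostic tests; the
learning pipeline itself never consumes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import SectorGeometry, VideoClip, polar_maps, sector_mask
from .labels import (
    A_LINES, COALESCENT, CONSOLIDATION, EFFUSION, GE3_BLINES, LT3_BLINES,
    SCATTERING, ConstraintSet, LabelVector, resolve_label_set,
    validate_label_vector,
)

MLS4 = resolve_label_set("mlS4")

MANIFEST_COLUMNS = ["path", "patient_id", "fps", "duration_s", "split",
                    *MLS4.labels,
                    "pole_row", "pole_col", "r_min", "r_max",
                    "theta_center", "opening_angle"]


@dataclass
class PhantomConfig:
    """Study conditions for the phantom dataset.

    Durations and frame rates follow the acquisition protocol being
    emulated (videos of 3-6 s at 25/30/60 fps; anything under 3 s is
    excluded); breathing sits at a typical resting ~0.25 Hz so one
    4 s clip spans a full respiratory cycle.
    """

    image_size: int = 128
    duration_range_s: tuple[float, float] = (3.0, 6.0)
    fps_choices: tuple[float, ...] = (25.0, 30.0, 60.0)
    breathing_hz: float = 0.25

    # geometry ranges (fractions of image size where sensible)
    opening_angle_deg: tuple[float, float] = (50.0, 75.0)
    pole_row_frac: tuple[float, float] = (-0.08, 0.04)
    pole_col_jitter_frac: float = 0.04
    r_min_frac: tuple[float, float] = (0.06, 0.12)
    r_max_fill: tuple[float, float] = (0.95, 1.0)

    # finding prevalences
    p_normal: float = 0.5
    p_a_lines_given_normal: float = 0.5
    b_line_probs: tuple[float, float, float, float] = (0.2, 0.3, 0.3, 0.2)
    #   (no B-lines, <3 B-lines, >=3 B-lines, coalescent)
    p_consolidation: float = 0.35
    p_effusion: float = 0.30

    # speckle / artifact appearance; widths are chosen so every finding
    # stays resolvable after nearest-neighbour downsampling to coarse
    # training grids (a few degrees of arc ~ a pixel at 32 px)
    speckle_grain_px: float = 1.5
    speckle_contrast: float = 0.30
    pleura_brightness: float = 0.9
    a_line_brightness: float = 0.55
    a_line_decay: float = 0.55
    b_line_brightness: float = 0.85
    b_line_sigma_deg: tuple[float, float] = (3.0, 4.5)
    coalescent_width_deg: tuple[float, float] = (12.0, 20.0)
    rock_amplitude_deg: tuple[float, float] = (1.0, 3.0)
    p_transient_b_line: float = 0.5
    transient_visible_fraction: float = 0.6
    with_z_lines: bool = False  # hard-negative rays that stop short of r_max

    def validate(self) -> None:
        if self.duration_range_s[0] < 3.0:
            raise ValueError("phantom durations shorter than 3 s are excluded")
        for p in (self.p_normal, self.p_a_lines_given_normal,
                  self.p_consolidation, self.p_effusion):
            if not 0 <= p <= 1:
                raise ValueError("prevalences must lie in [0, 1]")
        if abs(sum(self.b_line_probs) - 1.0) > 1e-9:
            raise ValueError("b_line_probs must sum to 1")


@dataclass
class PhantomSample:
    video: VideoClip
    geometry: SectorGeometry
    labels: LabelVector  # over mlS4
    patient_id: str
    labeled: bool
    meta: dict = field(default_factory=dict)


def sample_geometry(config: PhantomConfig, rng: np.random.Generator) -> SectorGeometry:
    s = config.image_size
    pole_row = rng.uniform(*config.pole_row_frac) * s
    pole_col = (s - 1) / 2 + rng.uniform(-1, 1) * config.pole_col_jitter_frac * s
    r_min = rng.uniform(*config.r_min_frac) * s
    r_max = (s - 1 - pole_row) * rng.uniform(*config.r_max_fill)
    alpha = math.radians(rng.uniform(*config.opening_angle_deg))
    return SectorGeometry(pole=(pole_row, pole_col), r_min=r_min, r_max=r_max,
                          theta_center=0.0, opening_angle=alpha)


def sample_labels(config: PhantomConfig, rng: np.random.Generator) -> LabelVector:
    """Draw a finding combination honouring the exclusivity rules.

    Normal videos carry exactly one of {scattering-only, A-lines};
    pathological ones carry at most one B-line finding plus
    independently sampled consolidation / effusion, redrawn if empty.
    """
    config.validate()
    if rng.random() < config.p_normal:
        positives = [A_LINES if rng.random() < config.p_a_lines_given_normal
                     else SCATTERING]
    else:
        while True:
            positives = []
            b_kind = rng.choice(4, p=np.asarray(config.b_line_probs))
            if b_kind == 1:
                positives.append(LT3_BLINES)
            elif b_kind == 2:
                positives.append(GE3_BLINES)
            elif b_kind == 3:
                positives.append(COALESCENT)
            if rng.random() < config.p_consolidation:
                positives.append(CONSOLIDATION)
            if rng.random() < config.p_effusion:
                positives.append(EFFUSION)
            if positives:
                break
    return LabelVector.from_positives(MLS4, positives)


def _smooth_noise(shape: tuple[int, int], grain: float,
                  rng: np.random.Generator) -> np.ndarray:
    n = gaussian_filter(rng.standard_normal(shape), grain)
    sd = n.std()
    return n / sd if sd > 0 else n


def render_video(labels: LabelVector, geometry: SectorGeometry,
                 config: PhantomConfig, rng: np.random.Generator,
                 duration_s: float | None = None,
                 fps: float | None = None) -> tuple[VideoClip, dict]:
    """Render one labeled phantom video; returns the clip and a ground-truth dict."""
    report = validate_label_vector(labels)
    if not report.valid:
        raise ValueError(f"invalid label combination: {report.violations}")
    g = geometry
    h = w = config.image_size
    if fps is None:
        fps = float(rng.choice(np.asarray(config.fps_choices)))
    if duration_s is None:
        duration_s = float(rng.uniform(*config.duration_range_s))
    n_frames = max(1, int(round(duration_s * fps)))

    pos = set(labels.positives())
    r, phi = polar_maps((h, w), g)
    mask = sector_mask((h, w), g)
    span = g.r_max - g.r_min
    r_pleura = g.r_min + rng.uniform(0.15, 0.25) * span
    depth = np.clip((r - g.r_min) / span, 0, None)

    # base tissue echo, brighter near the probe
    base = 0.42 * np.exp(-1.3 * depth) + 0.10
    base += config.pleura_brightness * np.exp(-0.5 * ((r - r_pleura) / 1.6) ** 2)

    meta: dict = {"fps": fps, "duration_s": n_frames / fps, "r_pleura": r_pleura}

    if A_LINES in pos:
        spacing = r_pleura - g.r_min  # reverberation period = skin-to-pleura depth
        spacing = max(spacing, 0.06 * span)
        radii = []
        k = 1
        while r_pleura + k * spacing < g.r_max - 2:
            amp = config.a_line_brightness * config.a_line_decay ** (k - 1)
            base += amp * np.exp(-0.5 * ((r - (r_pleura + k * spacing)) / 1.6) ** 2)
            radii.append(r_pleura + k * spacing)
            k += 1
        meta["a_line_radii"] = radii
        meta["a_line_spacing"] = spacing

    # B-line layout
    half = g.opening_angle / 2
    inner = 0.8 * half
    rays: list[dict] = []
    if LT3_BLINES in pos or GE3_BLINES in pos:
        sigma = math.radians(rng.uniform(*config.b_line_sigma_deg))
        rock = math.radians(max(config.rock_amplitude_deg))
        # keep rays resolvable in the time average: separation grows with
        # the ray width and the breathing rock, capping how many fit
        sep = max(math.radians(8.0), 2.6 * sigma + rock)
        span = 2 * inner
        if LT3_BLINES in pos:
            n_rays = int(rng.integers(1, 3))
        else:
            n_max = max(3, min(6, int(span / sep)))
            n_rays = int(rng.integers(3, n_max + 1))
        # jittered even slots guarantee the minimum angular separation
        slot = span / n_rays
        jitter = max(0.0, (slot - sep) / 2)
        angles = (-inner + (np.arange(n_rays) + 0.5) * slot
                  + rng.uniform(-jitter, jitter, size=n_rays))
        for a in angles:
            rays.append({
                "angle": float(a), "sigma": sigma,
                "rock": math.radians(rng.uniform(*config.rock_amplitude_deg)),
                "phase": rng.uniform(0, 2 * math.pi),
                "transient": bool(rng.random() < config.p_transient_b_line),
            })
    band = None
    if COALESCENT in pos:
        band = {
            "angle": float(rng.uniform(-0.6 * half, 0.6 * half)),
            "width": math.radians(rng.uniform(*config.coalescent_width_deg)),
            "rock": math.radians(rng.uniform(*config.rock_amplitude_deg)),
            "phase": rng.uniform(0, 2 * math.pi),
        }
    z_lines: list[dict] = []
    if config.with_z_lines and rng.random() < 0.5:
        for _ in range(int(rng.integers(1, 3))):
            z_lines.append({
                "angle": float(rng.uniform(-inner, inner)),
                "sigma": math.radians(rng.uniform(*config.b_line_sigma_deg)),
                "stop_frac": rng.uniform(0.35, 0.6),
            })
    meta["rays"] = rays
    meta["band"] = band
    meta["z_lines"] = z_lines

    below = (r > r_pleura).astype(np.float64)
    fade = np.exp(-0.6 * depth)  # rays attenuate gently with depth

    consol = None
    if CONSOLIDATION in pos:
        c_angle = rng.uniform(-0.6 * half, 0.6 * half)
        c_width = math.radians(rng.uniform(10.0, 18.0))
        c_depth = rng.uniform(0.25, 0.40) * span
        edge = 1 + 0.25 * _smooth_noise((h, w), 3.0, rng)
        inside = ((np.abs(phi - c_angle) < c_width * edge)
                  & (r > r_pleura) & (r < r_pleura + c_depth * edge))
        texture = 0.12 * _smooth_noise((h, w), 1.0, rng)
        consol = (inside, texture)
        meta["consolidation"] = {"angle": c_angle, "width": c_width, "depth": c_depth}

    effusion = None
    if EFFUSION in pos:
        e_angle = rng.uniform(-0.5 * half, 0.5 * half)
        e_width = math.radians(rng.uniform(12.0, 22.0))
        e_top = r_pleura + rng.uniform(0.04, 0.10) * span
        e_bot = e_top + rng.uniform(0.20, 0.35) * span
        inside = ((np.abs(phi - e_angle) < e_width) & (r > e_top) & (r < e_bot))
        effusion = (inside, e_bot)
        meta["effusion"] = {"angle": e_angle, "width": e_width,
                            "top": e_top, "bottom": e_bot}

    speckle_a = _smooth_noise((h, w), config.speckle_grain_px, rng)
    speckle_b = _smooth_noise((h, w), config.speckle_grain_px, rng)

    frames = np.empty((n_frames, h, w), dtype=np.float32)
    t = np.arange(n_frames) / fps
    breath = 2 * math.pi * config.breathing_hz * t
    presence = np.zeros((n_frames, max(1, len(rays))), dtype=bool) if rays else None

    for i in range(n_frames):
        img = base.copy()
        for j, ray in enumerate(rays):
            if ray["transient"]:
                gate = 0.5 * (1 + math.sin(breath[i] + ray["phase"]))
                if gate > config.transient_visible_fraction:
                    continue
            if presence is not None:
                presence[i, j] = True
            a = ray["angle"] + ray["rock"] * math.sin(breath[i] + ray["phase"])
            prof = np.exp(-0.5 * ((phi - a) / ray["sigma"]) ** 2)
            img += config.b_line_brightness * prof * below * fade
        if band is not None:
            a = band["angle"] + band["rock"] * math.sin(breath[i] + band["phase"])
            prof = 1 / (1 + np.exp((np.abs(phi - a) - band["width"] / 2)
                                   / (0.15 * band["width"])))
            img += 0.85 * config.b_line_brightness * prof * below * fade
        for z in z_lines:
            prof = np.exp(-0.5 * ((phi - z["angle"]) / z["sigma"]) ** 2)
            stop = g.r_min + z["stop_frac"] * span
            img += config.b_line_brightness * prof * below * fade * (r < stop)
        if consol is not None:
            inside, texture = consol
            img = np.where(inside, 0.35 * img + np.abs(texture), img)
        if effusion is not None:
            inside, e_bot = effusion
            img = np.where(inside, 0.05 * img, img)
            img += 0.5 * np.exp(-0.5 * ((r - e_bot) / 2.0) ** 2) * \
                (np.abs(phi - meta["effusion"]["angle"]) < meta["effusion"]["width"])
        mix = math.cos(breath[i]), math.sin(breath[i])
        speckle = 1 + config.speckle_contrast * (mix[0] * speckle_a + mix[1] * speckle_b)
        img = img * np.clip(speckle, 0.2, None)
        frames[i] = np.clip(img, 0.0, 1.0) * mask

    if presence is not None:
        meta["b_line_presence"] = presence
    return VideoClip(frames, fps), meta


def generate_samples(config: PhantomConfig, n_videos: int, labeled_fraction: float,
                     rng: np.random.Generator,
                     videos_per_patient: tuple[int, int] = (1, 12)) -> list[PhantomSample]:
    """Draw patients (1-12 videos each, mirroring a 12-field protocol) and render.

    The labeled flag is assigned at patient level so that approximately
    ``labeled_fraction`` of *videos* end up labeled.
    """
    if n_videos < 1:
        raise ValueError("need n_videos >= 1")
    config.validate()
    counts: list[int] = []
    while sum(counts) < n_videos:
        counts.append(int(rng.integers(videos_per_patient[0], videos_per_patient[1] + 1)))
    counts[-1] -= sum(counts) - n_videos
    if counts[-1] == 0:
        counts.pop()

    order = rng.permutation(len(counts))
    target = labeled_fraction * n_videos
    labeled_patients: set[int] = set()
    acc = 0
    for idx in order:
        if acc >= target:
            break
        labeled_patients.add(int(idx))
        acc += counts[int(idx)]

    samples: list[PhantomSample] = []
    for p_idx, n_vids in enumerate(counts):
        pid = f"P{p_idx:04d}"
        labeled = p_idx in labeled_patients
        for _ in range(n_vids):
            labels = sample_labels(config, rng)
            geom = sample_geometry(config, rng)
            video, meta = render_video(labels, geom, config, rng)
            samples.append(PhantomSample(video, geom, labels, pid, labeled, meta))
    return samples


def generate_dataset(config: PhantomConfig, n_videos: int, labeled_fraction: float,
                     rng: np.random.Generator, out_dir: str | Path,
                     videos_per_patient: tuple[int, int] = (1, 12)) -> pd.DataFrame:
    """Render a dataset to ``out_dir`` (npz frame stacks + manifest.csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(config, n_videos, labeled_fraction, rng,
                               videos_per_patient)
    rows = []
    for i, s in enumerate(samples):
        rel = f"video_{i:05d}.npz"
        np.savez_compressed(out / rel, frames=s.video.frames,
                            fps=np.float64(s.video.fps))
        row: dict = {
            "path": rel, "patient_id": s.patient_id, "fps": s.video.fps,
            "duration_s": round(s.video.duration_s, 6),
            "split": "labeled" if s.labeled else "unlabeled",
        }
        for lab, val in zip(MLS4.labels, s.labels.values):
            row[lab] = int(val) if s.labeled else ""
        row.update(s.geometry.to_dict())
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_video(dataset_dir: str | Path, rel_path: str) -> VideoClip:
    with np.load(Path(dataset_dir) / rel_path) as z:
        return VideoClip(z["frames"], float(z["fps"]))
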