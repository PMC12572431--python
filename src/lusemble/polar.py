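"""Beam-direction-preserving augmentation in polar coordinates.

Generic photometric/geometric augmentation can create ultrasound frames
that are physically impossible: A-lines and B-lines only ever occur
along the beam direction radiating from the probe's virtual origin.
The transforms here therefore act in polar space about the pole —
radial scaling (a change of imaging depth), an angular shift (rocking
the probe) and a linear contrast gain — before resampling back into
the Cartesian frame, which by construction keeps all content inside
the scan FOV and the background at exactly zero.  A horizontal flip
about the beam axis completes the set.

Polar grids put radius on rows and angle on columns.  Grid resolution
defaults to one row per pixel of radial span and one column per pixel
of arc length at the outer radius, so no detail is lost at the finest
Cartesian scale.  Resampling is bilinear; the nearest-neighbour rule is
reserved for the one-off 128x128 standardization resize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .core import SectorGeometry, VideoClip, sector_mask


@dataclass
class PolarClip:
    """A clip resampled on a regular (radius, angle) grid.

    ``grid`` is (T, R, Theta); row i sits at radius ``r_min + i*dr``,
    column j at angle ``theta_lo + j*dtheta``.
    """

    grid: np.ndarray
    geometry: SectorGeometry
    fps: float

    @property
    def n_r(self) -> int:
        return self.grid.shape[1]

    @property
    def n_theta(self) -> int:
        return self.grid.shape[2]

    @property
    def dr(self) -> float:
        g = self.geometry
        return (g.r_max - g.r_min) / (self.n_r - 1)

    @property
    def dtheta(self) -> float:
        return self.geometry.opening_angle / (self.n_theta - 1)


@dataclass(frozen=True)
class AugmentationPolicy:
    """Transform ranges and gate probabilities.

    ``train`` mode: scaling within +-30%, rotation up to +-10 deg and a
    linear contrast gain up to 0.25; each spatial transform is gated
    independently at 50% and the intensity transform at 15%.  ``weak``
    mode (pseudo-label generation): scaling +-7.5% and rotation
    +-2.5 deg always applied, flip at 50%, no contrast.
    """

    scale_pct: float = 0.30
    rot_deg: float = 10.0
    contrast_gain: float = 0.25
    p_spatial: float = 0.5
    p_intensity: float = 0.15
    p_flip: float = 0.5
    mode: str = "train"

    def __post_init__(self) -> None:
        if self.mode not in ("train", "weak"):
            raise ValueError("mode must be 'train' or 'weak'")
        if min(self.scale_pct, self.rot_deg, self.contrast_gain) < 0:
            raise ValueError("ranges must be nonnegative")
        for p in (self.p_spatial, self.p_intensity, self.p_flip):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def train(cls) -> "AugmentationPolicy":
        return cls()

    @classmethod
    def weak(cls) -> "AugmentationPolicy":
        return cls(scale_pct=0.075, rot_deg=2.5, contrast_gain=0.0,
                   p_spatial=1.0, p_intensity=0.0, p_flip=0.5, mode="weak")

    @classmethod
    def disabled(cls) -> "AugmentationPolicy":
        return cls(p_spatial=0.0, p_intensity=0.0, p_flip=0.0)


def default_polar_shape(g: SectorGeometry) -> tuple[int, int]:
    n_r = max(2, math.ceil(g.r_max - g.r_min))
    n_theta = max(2, math.ceil(g.opening_angle * g.r_max))
    return n_r, n_theta


def to_polar(clip: VideoClip, g: SectorGeometry,
             shape: tuple[int, int] | None = None) -> PolarClip:
    """Sample the clip on a regular (r, theta) grid about the pole."""
    if g.r_max <= g.r_min:
        raise ValueError("degenerate geometry: r_max <= r_min")
    n_r, n_theta = shape or default_polar_shape(g)
    r = np.linspace(g.r_min, g.r_max, n_r)
    th = np.linspace(g.theta_lo, g.theta_hi, n_theta)
    rows = g.pole[0] + r[:, None] * np.cos(th)[None, :]
    cols = g.pole[1] + r[:, None] * np.sin(th)[None, :]
    t = clip.frames.shape[0]
    # one trilinear call with integral time coordinates == per-frame bilinear
    coords = np.stack([
        np.broadcast_to(np.arange(t, dtype=np.float64)[:, None, None],
                        (t, n_r, n_theta)),
        np.broadcast_to(rows, (t, n_r, n_theta)),
        np.broadcast_to(cols, (t, n_r, n_theta)),
    ])
    grid = map_coordinates(clip.frames.astype(np.float64), coords, order=1,
                           mode="constant", cval=0.0).astype(np.float32)
    return PolarClip(grid, g, clip.fps)


def to_cartesian(p: PolarClip, shape: tuple[int, int]) -> VideoClip:
    """Inverse-map the polar grid into a Cartesian frame, zero outside the FOV."""
    g = p.geometry
    mask = sector_mask(shape, g)
    rr, cc = np.nonzero(mask)
    r = np.hypot(rr - g.pole[0], cc - g.pole[1])
    phi = np.arctan2(cc - g.pole[1], rr - g.pole[0])
    i = (r - g.r_min) / p.dr
    j = (phi - g.theta_lo) / p.dtheta
    t = p.grid.shape[0]
    npix = rr.size
    coords = np.stack([
        np.repeat(np.arange(t, dtype=np.float64), npix),
        np.tile(i, t),
        np.tile(j, t),
    ])
    vals = map_coordinates(p.grid.astype(np.float64), coords, order=1,
                           mode="constant", cval=0.0).reshape(t, npix)
    frames = np.zeros((t, *shape), dtype=np.float32)
    frames[:, rr, cc] = vals
    return VideoClip(np.clip(frames, 0.0, 1.0), p.fps)


def radial_scale(p: PolarClip, factor: float) -> PolarClip:
    """1D scale along the radial axis about the pole (the first polar row).

    Content at row index k moves to index k*factor; content pushed past
    the outer radius is cropped, and factor < 1 zero-fills the vacated
    far rows (preserving FOV closure).
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    n_r = p.n_r
    src = np.arange(n_r, dtype=np.float64) / factor
    t_idx = np.arange(p.grid.shape[0], dtype=np.float64)
    c_idx = np.arange(p.n_theta, dtype=np.float64)
    coords = np.stack(np.meshgrid(t_idx, src, c_idx, indexing="ij"))
    grid = map_coordinates(p.grid.astype(np.float64), coords, order=1,
                           mode="constant", cval=0.0).astype(np.float32)
    return replace(p, grid=grid)


def angular_shift(p: PolarClip, delta: float) -> PolarClip:
    """Translate along the angular axis by ``delta`` radians (probe rocking)."""
    shift = delta / p.dtheta
    src = np.arange(p.n_theta, dtype=np.float64) - shift
    t_idx = np.arange(p.grid.shape[0], dtype=np.float64)
    r_idx = np.arange(p.n_r, dtype=np.float64)
    coords = np.stack(np.meshgrid(t_idx, r_idx, src, indexing="ij"))
    grid = map_coordinates(p.grid.astype(np.float64), coords, order=1,
                           mode="constant", cval=0.0).astype(np.float32)
    return replace(p, grid=grid)


def linear_contrast(p: PolarClip, gain: float, pivot: float = 0.5) -> PolarClip:
    """Linear contrast with slope 1+gain about ``pivot``; zeros stay zero."""
    if gain == 0:
        return replace(p, grid=p.grid.copy())
    v = p.grid
    out = np.clip(pivot + (1.0 + gain) * (v - pivot), 0.0, 1.0).astype(np.float32)
    out[v == 0] = 0.0
    return replace(p, grid=out)


def horizontal_flip(clip: VideoClip, g: SectorGeometry) -> tuple[VideoClip, SectorGeometry]:
    """Mirror about the vertical line through the pole column.

    For a standardized clip the beam axis is vertical, so the sector
    maps onto itself (the beam-angle sign flips with it).
    """
    w = clip.frames.shape[2]
    pc = g.pole[1]
    flipped_g = replace(g, pole=(g.pole[0], pc), theta_center=-g.theta_center)
    if abs(2 * pc - (w - 1)) < 1e-9:
        return VideoClip(clip.frames[:, :, ::-1].copy(), clip.fps), flipped_g
    src = 2 * pc - np.arange(w, dtype=np.float64)
    t_idx = np.arange(clip.n_frames, dtype=np.float64)
    r_idx = np.arange(clip.frames.shape[1], dtype=np.float64)
    coords = np.stack(np.meshgrid(t_idx, r_idx, src, indexing="ij"))
    frames = map_coordinates(clip.frames.astype(np.float64), coords, order=1,
                             mode="constant", cval=0.0).astype(np.float32)
    return VideoClip(frames, clip.fps), flipped_g


@dataclass(frozen=True)
class AugmentationDraw:
    """One realized set of augmentation parameters (shared by all frames)."""

    scale: float | None
    shift_rad: float | None
    gain: float | None
    flip: bool


def draw_augmentation(policy: AugmentationPolicy,
                      rng: np.random.Generator) -> AugmentationDraw:
    if policy.mode == "weak":
        scale = 1.0 + rng.uniform(-policy.scale_pct, policy.scale_pct)
        shift = math.radians(rng.uniform(-policy.rot_deg, policy.rot_deg))
        gain = None
    else:
        scale = (1.0 + rng.uniform(-policy.scale_pct, policy.scale_pct)
                 if rng.random() < policy.p_spatial else None)
        shift = (math.radians(rng.uniform(-policy.rot_deg, policy.rot_deg))
                 if rng.random() < policy.p_spatial else None)
        gain = (rng.uniform(-policy.contrast_gain, policy.contrast_gain)
                if rng.random() < policy.p_intensity else None)
    flip = bool(rng.random() < policy.p_flip)
    return AugmentationDraw(scale, shift, gain, flip)


def apply_augmentation(clip: VideoClip, g: SectorGeometry,
                       draw: AugmentationDraw) -> tuple[VideoClip, SectorGeometry]:
    """Apply one parameter draw in the fixed order polar -> scale -> shift ->
    contrast -> Cartesian -> flip."""
    shape = clip.frames.shape[1:]
    p = to_polar(clip, g)
    if draw.scale is not None:
        p = radial_scale(p, draw.scale)
    if draw.shift_rad is not None:
        p = angular_shift(p, draw.shift_rad)
    if draw.gain is not None:
        p = linear_contrast(p, draw.gain)
    out = to_cartesian(p, shape)
    out_g = g
    if draw.flip:
        out, out_g = horizontal_flip(out, g)
        # a flip about an off-center pole resamples across the boundary;
        # re-mask so FOV closure stays exact
        mask = sector_mask(shape, out_g).astype(out.frames.dtype)
        out = VideoClip(out.frames * mask[None], out.fps)
    return out, out_g


def augment_clip(clip: VideoClip, g: SectorGeometry, policy: AugmentationPolicy,
                 rng: np.random.Generator) -> VideoClip:
    """Draw per-clip parameters from the policy and apply them to every frame."""
    out, _ = apply_augmentation(clip, g, draw_augmentation(policy, rng))
    return out
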