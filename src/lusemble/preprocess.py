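"""Sector geometry estimation, FOV masking and input standardization.

Ultrasound exports carry UI text, depth markers and vendor furniture
around the wedge-shaped scan sector; everything outside the field of
view is masked to zero before training.  The geometry estimator works
from per-pixel temporal variance: speckle makes the imaged sector
"alive" while the surroundings are static, so the largest active
connected component outlines the sector.  Its two straight flanks are
fit by trimmed least squares; their intersection gives the pole, their
directions the opening angle, and the component's radial extent the
two radii.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import SectorGeometry, VideoClip, polar_maps, sector_mask

#: ITU-R BT.601 luma weights, used when a color stack is supplied.
_BT601 = np.array([0.299, 0.587, 0.114], dtype=np.float32)


class SectorEstimationError(RuntimeError):
    """Raised when no plausible scan sector can be found in a video."""


def to_grayscale(frames: np.ndarray) -> np.ndarray:
    """Collapse a (T, H, W, 3) color stack to BT.601 luma; pass through grayscale."""
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 4 and frames.shape[-1] == 3:
        return frames @ _BT601
    return frames


def _fit_edge_line(points_row: np.ndarray, points_col: np.ndarray,
                   n_iter: int = 4, trim_px: float = 2.0) -> tuple[float, float]:
    """Least-squares line col = m*row + b with iterative outlier trimming.

    Trimming discards points curving away from the straight flank
    (the outer arc region at the bottom of the sector).
    """
    rows, cols = points_row.astype(float), points_col.astype(float)
    m, b = np.polyfit(rows, cols, 1)
    for _ in range(n_iter):
        resid = np.abs(cols - (m * rows + b))
        keep = resid <= max(trim_px, np.percentile(resid, 60))
        if keep.sum() < 5:
            break
        m, b = np.polyfit(rows[keep], cols[keep], 1)
    return float(m), float(b)


def estimate_sector_geometry(video: VideoClip,
                             variance_threshold: float = 1e-5,
                             min_active_fraction: float = 0.05,
                             coverage: float = 0.99,
                             area_slack: float = 0.10) -> SectorGeometry:
    """Estimate the scan-sector geometry of a bright-on-dark sector video.

    Raises :class:`SectorEstimationError` when the active area is below
    ``min_active_fraction`` of the frame or the fitted sector fails the
    self-consistency bounds (>= ``coverage`` of active pixels inside the
    sector, sector area at most ``1 + area_slack`` times the active area).
    """
    frames = video.frames
    if frames.shape[0] >= 2:
        activity = frames.var(axis=0)
    else:
        activity = frames[0] ** 2
    active = activity > variance_threshold
    h, w = active.shape
    if active.sum() < min_active_fraction * h * w:
        raise SectorEstimationError(
            f"no sector found: active area {active.sum() / (h * w):.1%} "
            f"below {min_active_fraction:.0%} of the frame")

    labeled, n_comp = ndimage.label(active)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n_comp + 1))
    comp = labeled == (1 + int(np.argmax(sizes)))

    comp_rows, comp_cols = np.nonzero(comp)
    row_lo, row_hi = comp_rows.min(), comp_rows.max()
    # flanks are straight only above the outer arc; use the upper 65%
    fit_hi = row_lo + max(5, int(0.65 * (row_hi - row_lo)))
    rows = np.arange(row_lo, fit_hi + 1)
    left = np.full(rows.size, -1)
    right = np.full(rows.size, -1)
    for i, rr in enumerate(rows):
        cc = comp_cols[comp_rows == rr]
        if cc.size:
            left[i], right[i] = cc.min(), cc.max()
    ok = left >= 0
    if ok.sum() < 8:
        raise SectorEstimationError("no sector found: component too small to fit")
    ml, bl = _fit_edge_line(rows[ok], left[ok] - 0.5)
    mr, br = _fit_edge_line(rows[ok], right[ok] + 0.5)
    if abs(ml - mr) < 1e-6:
        raise SectorEstimationError("no sector found: flanks are parallel")

    pole_row = (br - bl) / (ml - mr)
    pole_col = ml * pole_row + bl
    phi_l = np.arctan2(ml, 1.0)
    phi_r = np.arctan2(mr, 1.0)
    opening = phi_r - phi_l
    if opening <= 0:
        raise SectorEstimationError("no sector found: inverted flanks")
    theta_c = 0.5 * (phi_l + phi_r)

    radii = np.hypot(comp_rows - pole_row, comp_cols - pole_col)
    r_min = max(0.0, float(np.percentile(radii, 0.1)) - 1.0)
    r_max = float(np.percentile(radii, 99.9)) + 1.0
    geom = SectorGeometry(pole=(float(pole_row), float(pole_col)),
                          r_min=r_min, r_max=r_max,
                          theta_center=float(theta_c),
                          opening_angle=float(opening))

    mask = sector_mask((h, w), geom)
    inside = (mask & active).sum() / max(1, active.sum())
    area_ratio = mask.sum() / max(1, active.sum())
    if inside < coverage or area_ratio > 1 + area_slack:
        raise SectorEstimationError(
            f"sector fit fails coverage bound (coverage {inside:.3f}, "
            f"area ratio {area_ratio:.3f})")
    return geom


def apply_fov_mask(video: VideoClip, g: SectorGeometry) -> VideoClip:
    """Zero every pixel outside the sector; in-sector pixels are untouched."""
    mask = sector_mask(video.frames.shape[1:], g).astype(video.frames.dtype)
    return VideoClip(video.frames * mask[None], video.fps)


def standardize(video: VideoClip, g: SectorGeometry,
                size: int = 128) -> tuple[VideoClip, SectorGeometry]:
    """Resize to ``size x size`` by nearest neighbour, preserving aspect ratio.

    A single uniform scale is applied to both axes (nearest-neighbour
    keeps the original intensity palette and avoids smoothing) and the
    result is centered with zero padding.  The geometry is mapped by
    the same similarity transform.
    """
    t, h, w = video.frames.shape
    scale = size / max(h, w)
    h2, w2 = max(1, round(h * scale)), max(1, round(w * scale))
    src_r = np.clip(((np.arange(h2) + 0.5) / scale - 0.5).round().astype(int), 0, h - 1)
    src_c = np.clip(((np.arange(w2) + 0.5) / scale - 0.5).round().astype(int), 0, w - 1)
    resized = video.frames[:, src_r[:, None], src_c[None, :]]
    off_r, off_c = (size - h2) // 2, (size - w2) // 2
    out = np.zeros((t, size, size), dtype=video.frames.dtype)
    out[:, off_r:off_r + h2, off_c:off_c + w2] = resized
    new_g = g.scaled(scale, (float(off_r), float(off_c)))
    return VideoClip(out, video.fps), new_g


def preprocess_video(video: VideoClip, g: SectorGeometry | None = None,
                     size: int = 128) -> tuple[VideoClip, SectorGeometry]:
    """Full contract: grayscale -> geometry (estimated if absent) -> mask -> resize."""
    frames = to_grayscale(video.frames)
    video = VideoClip(np.clip(frames, 0.0, 1.0), video.fps)
    if g is None:
        g = estimate_sector_geometry(video)
    return standardize(apply_fov_mask(video, g), g, size=size)
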