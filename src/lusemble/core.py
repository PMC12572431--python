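"""Core in-memory containers shared by every stage of the pipeline.

Geometry convention
-------------------
Image coordinates are ``(row, col)`` with row 0 at the top.  Polar
coordinates are taken about the probe's virtual origin (the *pole*): a
pixel at ``(row, col)`` has radius ``r = hypot(row - pole_row, col -
pole_col)`` and beam angle ``phi = atan2(col - pole_col, row -
pole_row)``, so ``phi = 0`` points straight down the image (the typical
beam axis of a convex probe held at the top of the frame) and positive
angles lean towards larger columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class VideoClip:
    """A grayscale frame stack ``(T, H, W)`` with values in [0, 1]."""

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("a clip needs at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def copy(self) -> "VideoClip":
        return VideoClip(self.frames.copy(), self.fps)


@dataclass(frozen=True)
class SectorGeometry:
    """Sector-scan field of view: pole, radial span and opening angle.

    ``theta_center`` is the beam-axis direction in the angle convention
    of this module (0 = straight down); ``opening_angle`` is the full
    angular aperture in radians.
    """

    pole: tuple[float, float]  # (row, col), may lie outside the frame
    r_min: float
    r_max: float
    theta_center: float
    opening_angle: float

    def __post_init__(self) -> None:
        if not (0 <= self.r_min < self.r_max):
            raise ValueError("need 0 <= r_min < r_max")
        if not (0 < self.opening_angle < np.pi):
            raise ValueError("opening_angle must be in (0, pi)")

    @property
    def theta_lo(self) -> float:
        return self.theta_center - self.opening_angle / 2

    @property
    def theta_hi(self) -> float:
        return self.theta_center + self.opening_angle / 2

    def scaled(self, scale: float, offset: tuple[float, float]) -> "SectorGeometry":
        """Geometry after a uniform spatial scale followed by a translation."""
        pr, pc = self.pole
        return replace(
            self,
            pole=(pr * scale + offset[0], pc * scale + offset[1]),
            r_min=self.r_min * scale,
            r_max=self.r_max * scale,
        )

    def to_dict(self) -> dict:
        return {
            "pole_row": float(self.pole[0]),
            "pole_col": float(self.pole[1]),
            "r_min": float(self.r_min),
            "r_max": float(self.r_max),
            "theta_center": float(self.theta_center),
            "opening_angle": float(self.opening_angle),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SectorGeometry":
        return cls(
            pole=(float(d["pole_row"]), float(d["pole_col"])),
            r_min=float(d["r_min"]),
            r_max=float(d["r_max"]),
            theta_center=float(d["theta_center"]),
            opening_angle=float(d["opening_angle"]),
        )


def polar_maps(shape: tuple[int, int], g: SectorGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel radius and beam-angle maps for an ``(H, W)`` frame."""
    h, w = shape
    rows = np.arange(h, dtype=np.float64)[:, None] - g.pole[0]
    cols = np.arange(w, dtype=np.float64)[None, :] - g.pole[1]
    r = np.hypot(rows, cols)
    phi = np.arctan2(np.broadcast_to(cols, (h, w)), np.broadcast_to(rows, (h, w)))
    return r, phi


def sector_mask(shape: tuple[int, int], g: SectorGeometry) -> np.ndarray:
    """Boolean mask of pixels inside the sector FOV."""
    r, phi = polar_maps(shape, g)
    dphi = np.angle(np.exp(1j * (phi - g.theta_center)))
    return (
        (r >= g.r_min)
        & (r <= g.r_max)
        & (np.abs(dphi) <= g.opening_angle / 2)
    )
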