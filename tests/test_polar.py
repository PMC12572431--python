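"""Polar-space augmentation: coordinate mapping, FOV closure, policies."""

import math

import numpy as np
import pytest

import lusemble as lu
from lusemble.core import SectorGeometry, VideoClip, sector_mask
from lusemble.polar import (AugmentationPolicy, apply_augmentation,
                            default_polar_shape, draw_augmentation)


def _sector(size=64, r_min=6.0, r_max=58.0, alpha=1.1):
    return SectorGeometry(pole=(0.0, (size - 1) / 2), r_min=r_min,
                          r_max=r_max, theta_center=0.0, opening_angle=alpha)


def _smooth_clip(g, size=64, n_frames=2):
    yy, xx = np.mgrid[0:size, 0:size] / size
    base = 0.5 + 0.3 * np.sin(4 * yy) * np.cos(3 * xx)
    mask = sector_mask((size, size), g)
    frames = np.stack([(base * mask).astype(np.float32)] * n_frames)
    return VideoClip(frames, 25.0)


class TestToPolar:
    def test_concentric_arc_becomes_row_band(self):
        g = _sector()
        r, phi = np.hypot(*np.mgrid[0:64, 0:64] - np.array([[[g.pole[0]]],
                                                            [[g.pole[1]]]])), None
        rr = np.hypot(np.arange(64)[:, None] - g.pole[0],
                      np.arange(64)[None, :] - g.pole[1])
        arc = (np.abs(rr - 30) < 1.2).astype(np.float32)
        mask = sector_mask((64, 64), g)
        clip = VideoClip((arc * mask)[None], 25.0)
        p = lu.to_polar(clip, g)
        row_energy = p.grid[0].sum(axis=1)
        expected_row = round((30 - g.r_min) / p.dr)
        assert abs(int(np.argmax(row_energy)) - expected_row) <= 1

    def test_radial_ray_becomes_column_band(self):
        g = _sector()
        phi = np.arctan2(np.arange(64)[None, :] - g.pole[1],
                         np.arange(64)[:, None] - g.pole[0])
        theta0 = 0.2
        ray = (np.abs(phi - theta0) < 0.03).astype(np.float32)
        mask = sector_mask((64, 64), g)
        p = lu.to_polar(VideoClip((ray * mask)[None], 25.0), g)
        col_energy = p.grid[0][p.n_r // 2:].sum(axis=0)
        expected_col = round((theta0 - g.theta_lo) / p.dtheta)
        assert abs(int(np.argmax(col_energy)) - expected_col) <= 1

    def test_single_bright_pixel_maps_to_nearest_grid_cell(self):
        g = _sector()
        rng = np.random.default_rng(0)
        for _ in range(20):
            r0 = rng.uniform(g.r_min + 3, g.r_max - 3)
            t0 = rng.uniform(g.theta_lo + 0.1, g.theta_hi - 0.1)
            row = int(round(g.pole[0] + r0 * math.cos(t0)))
            col = int(round(g.pole[1] + r0 * math.sin(t0)))
            img = np.zeros((64, 64), dtype=np.float32)
            img[row, col] = 1.0
            p = lu.to_polar(VideoClip(img[None], 25.0), g)
            i, j = np.unravel_index(np.argmax(p.grid[0]), p.grid[0].shape)
            r_px = math.hypot(row - g.pole[0], col - g.pole[1])
            t_px = math.atan2(col - g.pole[1], row - g.pole[0])
            assert abs(i - (r_px - g.r_min) / p.dr) <= 1.5
            assert abs(j - (t_px - g.theta_lo) / p.dtheta) <= 1.5

    def test_degenerate_geometry_raises(self):
        g = _sector()
        clip = _smooth_clip(g)
        bad = SectorGeometry(pole=g.pole, r_min=5, r_max=50,
                             theta_center=0.0, opening_angle=1.0)
        object.__setattr__(bad, "r_max", 5.0)  # bypass constructor guard
        with pytest.raises(ValueError):
            lu.to_polar(clip, bad)


class TestRoundTrip:
    def test_round_trip_error_small_inside_and_zero_outside(self):
        g = _sector()
        clip = _smooth_clip(g)
        back = lu.to_cartesian(lu.to_polar(clip, g), (64, 64))
        mask = sector_mask((64, 64), g)
        assert np.abs(back.frames - clip.frames)[:, mask].mean() < 0.02
        assert np.abs(back.frames[:, ~mask]).max() == 0.0

    def test_all_zero_clip_stays_zero(self):
        g = _sector()
        zero = VideoClip(np.zeros((2, 64, 64), dtype=np.float32), 25.0)
        back = lu.to_cartesian(lu.to_polar(zero, g), (64, 64))
        assert np.abs(back.frames).max() == 0.0


class TestRadialScale:
    def test_identity_factor(self):
        g = _sector()
        p = lu.to_polar(_smooth_clip(g), g)
        assert np.allclose(lu.radial_scale(p, 1.0).grid, p.grid, atol=1e-6)

    def test_bright_row_moves_to_scaled_index(self):
        g = _sector()
        p = lu.to_polar(_smooth_clip(g), g)
        grid = np.zeros_like(p.grid)
        k = 20
        grid[:, k, :] = 1.0
        p2 = lu.radial_scale(type(p)(grid, p.geometry, p.fps), 1.2)
        assert abs(int(np.argmax(p2.grid[0].sum(axis=1))) - round(k * 1.2)) <= 1

    def test_composition_of_scalings(self):
        g = _sector()
        p = lu.to_polar(_smooth_clip(g), g)
        a = lu.radial_scale(lu.radial_scale(p, 1.15), 1.1)
        b = lu.radial_scale(p, 1.15 * 1.1)
        inner = slice(2, int(p.n_r / 1.3))
        assert np.abs(a.grid[:, inner] - b.grid[:, inner]).mean() < 0.03

    def test_shrink_zero_fills_far_rows(self):
        g = _sector()
        p = lu.to_polar(_smooth_clip(g), g)
        shrunk = lu.radial_scale(p, 0.5)
        assert np.abs(shrunk.grid[:, -(p.n_r // 3):, :]).max() == 0.0


class TestAngularShift:
    def test_zero_shift_identity(self):
        g = _sector()
        p = lu.to_polar(_smooth_clip(g), g)
        assert np.allclose(lu.angular_shift(p, 0.0).grid, p.grid, atol=1e-6)

    def test_ray_moves_by_delta_in_cartesian(self):
        g = _sector()
        phi = np.arctan2(np.arange(64)[None, :] - g.pole[1],
                         np.arange(64)[:, None] - g.pole[0])
        mask = sector_mask((64, 64), g)
        ray = ((np.abs(phi + 0.15) < 0.04) * mask).astype(np.float32)
        p = lu.to_polar(VideoClip(ray[None], 25.0), g)
        delta = 0.2
        shifted = lu.to_cartesian(lu.angular_shift(p, delta), (64, 64))
        rr, cc = np.nonzero(shifted.frames[0] > 0.5 * shifted.frames[0].max())
        angles = np.arctan2(cc - g.pole[1], rr - g.pole[0])
        assert abs(np.median(angles) - (-0.15 + delta)) < 0.02

    def test_shift_then_unshift_identity_on_overlap(self):
        g = _sector()
        p = lu.to_polar(_smooth_clip(g), g)
        back = lu.angular_shift(lu.angular_shift(p, 0.1), -0.1)
        cols = slice(int(0.15 / p.dtheta) + 2, -(int(0.15 / p.dtheta) + 2))
        rows = slice(1, -2)  # outermost rows carry the jagged r_max boundary
        assert np.abs(back.grid[:, rows, cols]
                      - p.grid[:, rows, cols]).max() < 0.02


class TestLinearContrast:
    def test_identity_gain(self):
        g = _sector()
        p = lu.to_polar(_smooth_clip(g), g)
        assert np.array_equal(lu.linear_contrast(p, 0.0).grid, p.grid)

    def test_pivot_fixed_point_and_mapped_values(self):
        g = _sector()
        grid = np.full((1, 5, 5), 0.5, dtype=np.float32)
        grid[0, 0, :] = 0.25
        grid[0, 1, :] = 0.75
        grid[0, 2, 0] = 0.0
        p = lu.PolarClip(grid, g, 25.0)
        out = lu.linear_contrast(p, 0.2).grid
        assert np.allclose(out[0, 3:], 0.5)
        assert np.allclose(out[0, 0], 0.20)
        assert np.allclose(out[0, 1], 0.80)
        assert out[0, 2, 0] == 0.0  # zeros preserved

    def test_clipping_to_unit_interval(self):
        g = _sector()
        grid = np.full((1, 2, 2), 0.99, dtype=np.float32)
        out = lu.linear_contrast(lu.PolarClip(grid, g, 25.0), 0.25).grid
        assert out.max() <= 1.0


class TestHorizontalFlip:
    def test_involution(self):
        g = _sector(size=63)  # odd size: pole column on the pixel grid
        clip = _smooth_clip(g, size=63)
        once, g1 = lu.horizontal_flip(clip, g)
        twice, g2 = lu.horizontal_flip(once, g1)
        assert np.allclose(twice.frames, clip.frames, atol=1e-6)
        assert g2.theta_center == g.theta_center

    def test_ray_mirrors_about_beam_axis(self):
        g = _sector(size=63)
        phi = np.arctan2(np.arange(63)[None, :] - g.pole[1],
                         np.arange(63)[:, None] - g.pole[0])
        mask = sector_mask((63, 63), g)
        ray = ((np.abs(phi - 0.25) < 0.04) * mask).astype(np.float32)
        flipped, _ = lu.horizontal_flip(VideoClip(ray[None], 25.0), g)
        rr, cc = np.nonzero(flipped.frames[0] > 0.5)
        angles = np.arctan2(cc - g.pole[1], rr - g.pole[0])
        assert abs(np.median(angles) + 0.25) < 0.02


class TestAugmentClip:
    def test_disabled_policy_is_near_identity(self, standardized_sample):
        std, g2, _ = standardized_sample
        clip = lu.extract_clip(std, 0.0, lu.ClipSpec(n_frames=4, rate_hz=8.0))
        out = lu.augment_clip(clip, g2, AugmentationPolicy.disabled(),
                              np.random.default_rng(0))
        mask = sector_mask(clip.frames.shape[1:], g2)
        inner = mask & (np.hypot(*np.mgrid[0:32, 0:32]
                                 - np.array([[[g2.pole[0]]], [[g2.pole[1]]]]))
                        < g2.r_max - 2)
        assert np.abs(out.frames - clip.frames)[:, inner].mean() < 0.06

    def test_weak_policy_always_scales_and_shifts_never_contrasts(self):
        rng = np.random.default_rng(1)
        draws = [draw_augmentation(AugmentationPolicy.weak(), rng)
                 for _ in range(50)]
        assert all(d.scale is not None and d.shift_rad is not None
                   for d in draws)
        assert all(d.gain is None for d in draws)
        assert all(abs(d.scale - 1) <= 0.075 + 1e-12 for d in draws)
        assert all(abs(d.shift_rad) <= math.radians(2.5) + 1e-12
                   for d in draws)
        flips = sum(d.flip for d in draws)
        assert 10 < flips < 40

    def test_fixed_seed_reproducible(self, standardized_sample):
        std, g2, _ = standardized_sample
        clip = lu.extract_clip(std, 0.0, lu.ClipSpec(n_frames=4, rate_hz=8.0))
        a = lu.augment_clip(clip, g2, AugmentationPolicy.train(),
                            np.random.default_rng(42))
        b = lu.augment_clip(clip, g2, AugmentationPolicy.train(),
                            np.random.default_rng(42))
        assert np.array_equal(a.frames, b.frames)

    def test_fov_closure_for_any_draw(self, standardized_sample):
        std, g2, _ = standardized_sample
        clip = lu.extract_clip(std, 0.0, lu.ClipSpec(n_frames=4, rate_hz=8.0))
        rng = np.random.default_rng(2)
        mask = sector_mask(clip.frames.shape[1:], g2)
        _, flip_g = lu.horizontal_flip(clip, g2)
        flip_mask = sector_mask(clip.frames.shape[1:], flip_g)
        for _ in range(10):
            out = lu.augment_clip(clip, g2, AugmentationPolicy.train(), rng)
            assert np.abs(out.frames[:, ~(mask | flip_mask)]).max() == 0.0

    def test_temporal_coherence_single_draw_per_clip(self, standardized_sample):
        """Frame-to-frame differences of the augmented clip track those of
        the input (parameters are shared across frames, not redrawn)."""
        std, g2, _ = standardized_sample
        clip = lu.extract_clip(std, 0.0, lu.ClipSpec(n_frames=8, rate_hz=8.0))
        out = lu.augment_clip(clip, g2, AugmentationPolicy.train(),
                              np.random.default_rng(3))
        d_in = np.abs(np.diff(clip.frames, axis=0)).mean(axis=(1, 2))
        d_out = np.abs(np.diff(out.frames, axis=0)).mean(axis=(1, 2))
        assert np.corrcoef(d_in, d_out)[0, 1] > 0.5

    def test_arcs_stay_rows_and_rays_stay_columns(self):
        """Label-preservation proxy: after a spatial augmentation, an
        A-line arc is still row-aligned and a B-line ray column-aligned
        in polar space."""
        g = _sector()
        rr = np.hypot(np.arange(64)[:, None] - g.pole[0],
                      np.arange(64)[None, :] - g.pole[1])
        phi = np.arctan2(np.arange(64)[None, :] - g.pole[1],
                         np.arange(64)[:, None] - g.pole[0])
        mask = sector_mask((64, 64), g)
        arc = ((np.abs(rr - 30) < 1.2) * mask).astype(np.float32)
        ray = ((np.abs(phi - 0.1) < 0.04) * mask).astype(np.float32)
        from lusemble.polar import AugmentationDraw
        draw = AugmentationDraw(scale=1.2, shift_rad=0.1, gain=None, flip=False)
        for img, axis in ((arc, 1), (ray, 0)):
            out, out_g = apply_augmentation(VideoClip(img[None], 25.0), g, draw)
            p = lu.to_polar(out, out_g)
            half = p.grid[0][p.n_r // 2:] if axis == 0 else p.grid[0]
            energy = half.sum(axis=axis)
            occupied = np.nonzero(energy > 0.4 * energy.max())[0]
            assert np.ptp(occupied) <= max(3, int(0.1 * energy.size))


def test_default_polar_shape_matches_resolution_rule():
    g = _sector(r_min=6, r_max=58, alpha=1.1)
    n_r, n_t = default_polar_shape(g)
    assert n_r == math.ceil(58 - 6)
    assert n_t == math.ceil(1.1 * 58)
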