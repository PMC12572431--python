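"""Phantom generator: label sampling, rendering contracts, dataset plumbing."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks

import lusemble as lu
from lusemble.core import sector_mask
from lusemble.labels import (A_LINES, GE3_BLINES, LT3_BLINES, SCATTERING,
                             NORMAL_FINDINGS)
from lusemble.phantom import MLS4, load_video, sample_geometry
from lusemble.polar import to_polar


class TestSampleLabels:
    def test_every_draw_is_valid(self, phantom_cfg):
        rng = np.random.default_rng(0)
        for _ in range(300):
            v = lu.sample_labels(phantom_cfg, rng)
            report = lu.validate_label_vector(v)
            assert report.valid and not report.empty

    def test_normal_draws_have_exactly_one_normal_finding(self, phantom_cfg):
        rng = np.random.default_rng(1)
        for _ in range(200):
            pos = set(lu.sample_labels(phantom_cfg, rng).positives())
            n_normal = len(pos & set(NORMAL_FINDINGS))
            assert n_normal in (0, 1)
            if n_normal == 1:
                assert len(pos) == 1

    def test_prevalences_within_three_sigma(self, phantom_cfg):
        """Empirical finding frequencies match the configured probabilities
        (binomial 3-sigma bands; the pathological redraw slightly inflates
        consolidation/effusion, so those are checked against the
        renormalized expectation)."""
        rng = np.random.default_rng(2)
        n = 10_000
        normal = 0
        for _ in range(n):
            pos = set(lu.sample_labels(phantom_cfg, rng).positives())
            normal += bool(pos & set(NORMAL_FINDINGS))
        p = phantom_cfg.p_normal
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(normal / n - p) < 3 * sigma


class TestRenderVideo:
    def test_background_outside_sector_is_zero(self, rendered_sample):
        video, geometry, *_ = rendered_sample
        mask = sector_mask(video.frames.shape[1:], geometry)
        assert np.abs(video.frames[:, ~mask]).max() == 0.0

    def test_scattering_only_has_no_arcs_or_rays(self, phantom_cfg):
        rng = np.random.default_rng(3)
        labels = lu.LabelVector.from_positives(MLS4, [SCATTERING])
        g = sample_geometry(phantom_cfg, rng)
        video, meta = lu.render_video(labels, g, phantom_cfg, rng,
                                      duration_s=3.0)
        assert "a_line_radii" not in meta and not meta["rays"]
        assert meta["band"] is None

    def test_a_line_radii_equally_spaced_below_pleura(self, phantom_cfg):
        rng = np.random.default_rng(4)
        labels = lu.LabelVector.from_positives(MLS4, [A_LINES])
        g = sample_geometry(phantom_cfg, rng)
        _, meta = lu.render_video(labels, g, phantom_cfg, rng, duration_s=3.0)
        radii = np.array(meta["a_line_radii"])
        assert radii.size >= 1
        expected = meta["r_pleura"] + meta["a_line_spacing"] * np.arange(
            1, radii.size + 1)
        assert np.allclose(radii, expected)

    @pytest.mark.parametrize("finding, lo, hi", [(LT3_BLINES, 1, 2),
                                                 (GE3_BLINES, 3, 6)])
    def test_ray_count_matches_label(self, phantom_cfg, finding, lo, hi):
        rng = np.random.default_rng(5)
        labels = lu.LabelVector.from_positives(MLS4, [finding])
        for _ in range(5):
            g = sample_geometry(phantom_cfg, rng)
            _, meta = lu.render_video(labels, g, phantom_cfg, rng,
                                      duration_s=3.0)
            assert lo <= len(meta["rays"]) <= hi

    def test_ray_centers_detectable_in_time_averaged_polar_image(self):
        """Peak counting on the angular profile recovers the drawn ray
        count (transience disabled so every ray is always on)."""
        cfg = lu.PhantomConfig(image_size=64, duration_range_s=(3.0, 3.5),
                               fps_choices=(25.0,), p_transient_b_line=0.0)
        rng = np.random.default_rng(6)
        labels = lu.LabelVector.from_positives(MLS4, [GE3_BLINES])
        g = sample_geometry(cfg, rng)
        video, meta = lu.render_video(labels, g, cfg, rng, duration_s=3.0)
        polar = to_polar(lu.VideoClip(video.frames.mean(axis=0,
                                                        keepdims=True),
                                      video.fps), g)
        below = polar.grid[0][polar.n_r // 3:, :]
        profile = below.mean(axis=0)
        peaks, _ = find_peaks(profile, prominence=0.05)
        assert len(peaks) == len(meta["rays"])

    def test_invalid_label_combination_rejected(self, phantom_cfg):
        rng = np.random.default_rng(7)
        bad = lu.LabelVector.from_positives(MLS4, [A_LINES, GE3_BLINES])
        with pytest.raises(ValueError):
            lu.render_video(bad, sample_geometry(phantom_cfg, rng),
                            phantom_cfg, rng)

    def test_transient_b_lines_vanish_in_some_frames(self):
        cfg = lu.PhantomConfig(image_size=64, fps_choices=(25.0,),
                               p_transient_b_line=1.0,
                               transient_visible_fraction=0.5)
        rng = np.random.default_rng(8)
        labels = lu.LabelVector.from_positives(MLS4, [GE3_BLINES])
        _, meta = lu.render_video(labels, sample_geometry(cfg, rng), cfg, rng,
                                  duration_s=4.0)
        presence = meta["b_line_presence"]
        assert presence.any() and not presence.all()


class TestGenerateDataset:
    def test_manifest_counts_and_patient_granularity(self, phantom_cfg, tmp_path):
        rng = np.random.default_rng(9)
        man = lu.generate_dataset(phantom_cfg, 40, 0.45, rng, tmp_path)
        assert len(man) == 40
        counts = man.groupby("patient_id").size()
        assert counts.between(1, 12).all()
        # labeled flag is patient-level
        assert (man.groupby("patient_id")["split"].nunique() == 1).all()
        labeled = (man["split"] == "labeled").sum()
        assert abs(labeled - 18) <= 12  # within one patient of the target

    def test_labeled_fraction_one_has_no_unlabeled_rows(self, phantom_cfg, tmp_path):
        rng = np.random.default_rng(10)
        man = lu.generate_dataset(phantom_cfg, 10, 1.0, rng, tmp_path / "a")
        assert (man["split"] == "labeled").all()

    def test_same_seed_bit_identical(self, phantom_cfg, tmp_path):
        m1 = lu.generate_dataset(phantom_cfg, 6, 0.5,
                                 np.random.default_rng(11), tmp_path / "r1")
        m2 = lu.generate_dataset(phantom_cfg, 6, 0.5,
                                 np.random.default_rng(11), tmp_path / "r2")
        pd.testing.assert_frame_equal(m1, m2)
        for rel in m1["path"]:
            v1 = load_video(tmp_path / "r1", rel)
            v2 = load_video(tmp_path / "r2", rel)
            assert np.array_equal(v1.frames, v2.frames)

    def test_unlabeled_rows_have_empty_label_cells(self, phantom_cfg, tmp_path):
        rng = np.random.default_rng(12)
        man = lu.generate_dataset(phantom_cfg, 20, 0.3, rng, tmp_path / "u")
        on_disk = pd.read_csv(tmp_path / "u" / "manifest.csv")
        unl = on_disk[on_disk["split"] == "unlabeled"]
        assert len(unl) > 0
        assert unl[list(MLS4.labels)].isna().all().all()


def test_linear_probe_separates_a_lines_from_b_lines(phantom_cfg):
    """A-line and >=3-B-line phantoms are linearly separable from
    time-averaged polar features (guards against unlearnable fixtures)."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import cross_val_score

    rng = np.random.default_rng(13)
    X, y = [], []
    for cls, finding in enumerate((A_LINES, GE3_BLINES)):
        labels = lu.LabelVector.from_positives(MLS4, [finding])
        for _ in range(30):
            g = sample_geometry(phantom_cfg, rng)
            video, _ = lu.render_video(labels, g, phantom_cfg, rng,
                                       duration_s=3.0)
            mean = lu.VideoClip(video.frames.mean(axis=0, keepdims=True),
                                video.fps)
            polar = to_polar(mean, g, shape=(24, 24))
            X.append(polar.grid[0].ravel())
            y.append(cls)
    acc = cross_val_score(LogisticRegression(max_iter=2000), np.array(X),
                          np.array(y), cv=3).mean()
    assert acc >= 0.95
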