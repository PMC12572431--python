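"""Hierarchy-aware ensemble aggregation and prediction."""

import itertools

import numpy as np
import pytest

from lusemble.clips import ClipSpec
from lusemble.core import SectorGeometry, VideoClip
from lusemble.ensemble import (EnsembleMember, EnsembleSpec, aggregate_member,
                               build_repetition_ensemble, ensemble_predict)
from lusemble.labels import (LabelError, build_default_hierarchy,
                             low_to_high_map, resolve_label_set)

H = build_default_hierarchy()
ML_SETS = ["mlS1", "mlS2", "mlS3", "mlS4"]
CL_SETS = ["cLS1", "cLS2", "cLS3", "cLS4"]


def _compatible_pairs(names):
    for a, b in itertools.product(names, repeat=2):
        try:
            low_to_high_map(resolve_label_set(a), resolve_label_set(b), H)
        except LabelError:
            continue
        yield a, b


def _oracle(scores, member, target, mode):
    """Enumerate the hierarchy mapping explicitly, label by label."""
    out = []
    for t in target.labels:
        if t in member.labels:
            out.append(scores[member.index(t)])
            continue
        t_leaves = set(H.leaves(t))
        vals = [scores[member.index(s)] for s in member.labels
                if set(H.leaves(s)) <= t_leaves]
        out.append(sum(vals) if mode == "categorical" else max(vals))
    return np.array(out)


class TestAggregateMember:
    def test_categorical_sum_rule(self):
        cls4, cls1 = resolve_label_set("cLS4"), resolve_label_set("cLS1")
        scores = np.array([0.2, 0.3, 0.1, 0.4])
        out = aggregate_member(scores, cls4, cls1, "categorical")
        assert np.allclose(out, [0.5, 0.5])  # Normal = S + A

    def test_multilabel_max_rule(self):
        mls4, mls1 = resolve_label_set("mlS4"), resolve_label_set("mlS1")
        scores = np.zeros(7)
        scores[mls4.index("Consolidation")] = 0.4
        scores[mls4.index("Pleural effusion")] = 0.7
        out = aggregate_member(scores, mls4, mls1, "multi-label")
        assert out[mls1.index("Other pathologies")] == 0.7

    def test_member_equals_target_identity(self):
        mls1 = resolve_label_set("mlS1")
        scores = np.random.default_rng(0).random(5)
        assert np.array_equal(
            aggregate_member(scores, mls1, mls1, "multi-label"), scores)

    @pytest.mark.parametrize("mode, names", [("multi-label", ML_SETS),
                                             ("categorical", CL_SETS)])
    def test_matches_enumeration_oracle_all_pairs(self, mode, names):
        rng = np.random.default_rng(1)
        pairs = list(_compatible_pairs(names))
        assert pairs, "no compatible pairs found"
        for a, b in pairs:
            src, tgt = resolve_label_set(a), resolve_label_set(b)
            for _ in range(20):
                scores = rng.random(len(src))
                if mode == "categorical":
                    scores = scores / scores.sum()
                got = aggregate_member(scores, src, tgt, mode)
                assert np.allclose(got, _oracle(scores, src, tgt, mode)), (a, b)

    def test_categorical_conserves_probability_mass(self):
        rng = np.random.default_rng(2)
        for a, b in _compatible_pairs(CL_SETS):
            src, tgt = resolve_label_set(a), resolve_label_set(b)
            s = rng.random(len(src))
            s /= s.sum()
            assert np.isclose(aggregate_member(s, src, tgt,
                                               "categorical").sum(), 1.0)

    def test_multilabel_high_level_dominates_low_levels(self):
        rng = np.random.default_rng(3)
        mls4, mls1 = resolve_label_set("mlS4"), resolve_label_set("mlS1")
        s = rng.random(7)
        out = aggregate_member(s, mls4, mls1, "multi-label")
        m = low_to_high_map(mls4, mls1, H)
        for t, srcs in m.items():
            assert all(out[mls1.index(t)] >= s[mls4.index(x)] for x in srcs)

    def test_incompatible_sets_raise(self):
        with pytest.raises(LabelError):
            aggregate_member(np.zeros(2), resolve_label_set("cLS1"),
                             resolve_label_set("cLS4"), "categorical")


class _TableModel:
    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=np.float64)

    def predict_proba(self, x):
        return np.tile(self.scores, (x.shape[0], 1))


def _dummy_video():
    size = 24
    g = SectorGeometry(pole=(0.0, (size - 1) / 2), r_min=2.0, r_max=size - 2.0,
                       theta_center=0.0, opening_angle=1.0)
    frames = np.random.default_rng(4).random((10, size, size),
                                             dtype=np.float32)
    return VideoClip(frames, 8.0), g


class TestEnsemblePredict:
    def test_single_member_identity(self):
        mls1 = resolve_label_set("mlS1")
        video, _ = _dummy_video()
        member = EnsembleMember(mls1, model=_TableModel([0.1, 0.2, 0.3,
                                                         0.4, 0.5]))
        spec = EnsembleSpec([member], mls1, "multi-label")
        out = ensemble_predict(spec, video,
                               clip_spec=ClipSpec(n_frames=8, rate_hz=8.0))
        assert np.allclose(out, [0.1, 0.2, 0.3, 0.4, 0.5])

    def test_categorical_output_sums_to_one(self):
        cls1, cls4 = resolve_label_set("cLS1"), resolve_label_set("cLS4")
        video, _ = _dummy_video()
        members = [EnsembleMember(cls1, model=_TableModel([0.6, 0.4])),
                   EnsembleMember(cls4, model=_TableModel([0.1, 0.2,
                                                           0.3, 0.4]))]
        spec = EnsembleSpec(members, cls1, "categorical")
        out = ensemble_predict(spec, video,
                               clip_spec=ClipSpec(n_frames=8, rate_hz=8.0))
        assert np.isclose(out.sum(), 1.0)
        # mean of the verbatim (0.6,0.4) and the lifted (0.3,0.7)
        assert np.allclose(out, [0.45, 0.55])

    def test_four_member_multi_output_to_high_level(self):
        """Members on mlS1..mlS4 jointly predicting mlS1: the ensemble
        mean sits inside the envelope of member-aggregated scores."""
        mls1 = resolve_label_set("mlS1")
        video, _ = _dummy_video()
        rng = np.random.default_rng(5)
        members, lifted = [], []
        for name in ML_SETS:
            ls = resolve_label_set(name)
            s = rng.random(len(ls))
            members.append(EnsembleMember(ls, model=_TableModel(s)))
            lifted.append(aggregate_member(s, ls, mls1, "multi-label"))
        spec = EnsembleSpec(members, mls1, "multi-label")
        out = ensemble_predict(spec, video,
                               clip_spec=ClipSpec(n_frames=8, rate_hz=8.0))
        lifted = np.array(lifted)
        assert np.allclose(out, lifted.mean(axis=0))
        assert np.all(out >= lifted.min(axis=0) - 1e-12)
        assert np.all(out <= lifted.max(axis=0) + 1e-12)

    def test_score_table_mode(self):
        mls1 = resolve_label_set("mlS1")
        member = EnsembleMember(mls1, score_table={7: np.full(5, 0.2)})
        spec = EnsembleSpec([member], mls1, "multi-label")
        assert np.allclose(ensemble_predict(spec, None, key=7), 0.2)

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            EnsembleSpec([], resolve_label_set("mlS1"), "multi-label")

    def test_repetition_requires_matching_sets(self):
        m = EnsembleMember(resolve_label_set("mlS4"), score_table={})
        with pytest.raises(ValueError):
            EnsembleSpec([m], resolve_label_set("mlS1"), "multi-label",
                         strategy="model-repetition")


def test_repetition_ensemble_members_differ(monkeypatch):
    """Independently-seeded members end with distinct weights."""
    from lusemble.network import NetworkSpec
    from lusemble.polar import AugmentationPolicy
    from lusemble.training import TrainConfig, TrainingRecord

    video, g = _dummy_video()
    cls1 = resolve_label_set("cLS1")
    rng = np.random.default_rng(6)
    records = [TrainingRecord(VideoClip(rng.random((10, 24, 24),
                                                   dtype=np.float32), 8.0),
                              g, np.eye(2)[i % 2]) for i in range(4)]
    cfg = TrainConfig(epochs=1, batch_size=4, lr=1e-3, smoothing=0.0,
                      mode="categorical",
                      clip_spec=ClipSpec(n_frames=8, rate_hz=8.0),
                      augment=AugmentationPolicy.disabled(), seed=0)
    net = NetworkSpec(widths=(4, 4, 4, 8, 8), input_shape=(8, 24, 24),
                      head="softmax", n_outputs=2, tiny=True)
    with pytest.warns(UserWarning):
        build_repetition_ensemble(records, cls1, cfg, k=1, network=net)
    spec = build_repetition_ensemble(records, cls1, cfg, k=2, network=net)
    w0 = spec.members[0].model.params()[0].value
    w1 = spec.members[1].model.params()[0].value
    assert not np.array_equal(w0, w1)
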