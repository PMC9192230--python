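"""Mean-teacher losses, EMA dynamics and the dataset partition."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import rel_entr

from uatransnet.network import NetworkConfig, build_classifier
from uatransnet.phantom import PhantomSpec, generate_dataset
from uatransnet.semisupervised import (MeanTeacherConfig, TeacherStudentState,
                                       ema_update, js_consistency_loss,
                                       kl_divergence, mean_teacher_step,
                                       partition_dataset, supervised_loss,
                                       total_loss, train_mean_teacher)

NET = NetworkConfig(depth=2, base_width=8, image_size=(32, 32), use_mgam=False)


# ------------------------------------------------------------- losses


def test_cross_entropy_hand_values():
    assert supervised_loss([1], [0.8]) == pytest.approx(-math.log(0.8), abs=1e-6)
    assert supervised_loss([1, 0], [0.8, 0.2]) == pytest.approx(-math.log(0.8), abs=1e-6)
    assert supervised_loss([1, 0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-5)
    with pytest.raises(ValueError):
        supervised_loss([1, 0], [0.5])


def test_kl_hand_value_and_scipy_agreement(rng):
    # 0.5 ln 2 + 0.5 ln(2/3)
    assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
        0.5 * math.log(2) + 0.5 * math.log(2 / 3), abs=1e-9)
    p = rng.dirichlet(np.ones(4))
    q = rng.dirichlet(np.ones(4))
    assert kl_divergence(p, q) == pytest.approx(rel_entr(p, q).sum(), abs=1e-6)


def test_kl_self_is_zero_and_invalid_dist_rejected():
    assert kl_divergence([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError, match="not a probability"):
        kl_divergence([0.5, 0.6], [0.5, 0.5])


@given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
def test_kl_nonnegative_and_js_symmetric_bounded(p, q):
    P, Q = [p, 1 - p], [q, 1 - q]
    assert kl_divergence(P, Q) >= -1e-12
    js = js_consistency_loss(P, Q)
    assert js == pytest.approx(js_consistency_loss(Q, P), abs=1e-12)
    assert -1e-12 <= js <= math.log(2) + 1e-12


def test_js_approaches_ln2_for_disjoint_masses():
    eps = 1e-7
    js = js_consistency_loss([1 - eps, eps], [eps, 1 - eps])
    assert js == pytest.approx(math.log(2), abs=1e-4)
    assert js_consistency_loss([0.4, 0.6], [0.4, 0.6]) == pytest.approx(0, abs=1e-12)


def test_total_loss_is_weighted_sum():
    assert total_loss(0.3, 0.2) == pytest.approx(0.5)
    assert total_loss(0.3, 0.2, weight=0.0) == pytest.approx(0.3)
    assert total_loss(0.7, 0.0) == pytest.approx(0.7)


# ------------------------------------------------------------- EMA


def make_state(seed=0, decay=0.99):
    return TeacherStudentState(build_classifier(NET, seed),
                               build_classifier(NET, seed + 1), ema_decay=decay)


def test_ema_boundary_decays():
    state = make_state(decay=1.0)
    before = state.teacher.state_dict()
    ema_update(state)
    assert all(np.array_equal(before[k], v)
               for k, v in state.teacher.state_dict().items())
    state = make_state(decay=0.0)
    ema_update(state)
    student = state.student.state_dict()
    assert all(np.allclose(student[k], v)
               for k, v in state.teacher.state_dict().items())


def test_ema_direct_arithmetic():
    state = make_state(decay=0.99)
    for _, p in state.teacher.named_parameters():
        p.data[:] = 1.0
    for _, p in state.student.named_parameters():
        p.data[:] = 0.0
    ema_update(state)
    for _, p in state.teacher.named_parameters():
        assert np.allclose(p.data, 0.99)


def test_ema_is_convex_combination(rng):
    state = make_state(decay=0.7)
    before = state.teacher.state_dict()
    student = state.student.state_dict()
    ema_update(state)
    for k, after in state.teacher.state_dict().items():
        lo = np.minimum(before[k], student[k]) - 1e-6
        hi = np.maximum(before[k], student[k]) + 1e-6
        assert ((after >= lo) & (after <= hi)).all()


def test_teacher_converges_geometrically_to_frozen_student():
    state = make_state(decay=0.9)
    student = state.student.state_dict()
    dist = []
    for _ in range(5):
        ema_update(state)
        dist.append(sum(np.abs(v - student[k]).sum()
                        for k, v in state.teacher.state_dict().items()))
    ratios = [b / a for a, b in zip(dist, dist[1:])]
    assert all(r == pytest.approx(0.9, abs=1e-3) for r in ratios)


def test_incongruent_models_rejected():
    with pytest.raises(ValueError, match="congruent"):
        TeacherStudentState(build_classifier(NET, 0),
                            build_classifier(NetworkConfig(
                                depth=3, base_width=8, image_size=(32, 32)), 0))


# ------------------------------------------------------------- training


def _phantom_images(n, seed, easy):
    spec = (PhantomSpec(image_size=(32, 32), semi_axis_range=(6, 10),
                        noise_sd=0.03, edge_blur_sigma=0.5)
            if easy else
            PhantomSpec(image_size=(32, 32), semi_axis_range=(2, 4),
                        noise_sd=0.12, edge_blur_sigma=2.5,
                        fg_intensity=0.55, bg_intensity=0.35))
    return np.stack([it.image for it in generate_dataset(spec, n, seed)])


def test_step_reduces_to_supervised_without_consistency(rng):
    from uatransnet.nn import Adam
    state = make_state(seed=2)
    opt = Adam(state.student.parameters())
    x = _phantom_images(4, 5, True)[:, None].astype(np.float32)
    y = np.ones(4)
    losses = mean_teacher_step((x, y), None, state, opt,
                               MeanTeacherConfig(consistency_weight=0.0), rng)
    assert "consistency" not in losses
    assert losses["total"] == pytest.approx(losses["supervised"])
    with pytest.raises(ValueError, match="nonempty"):
        mean_teacher_step((np.empty((0, 1, 32, 32)), np.empty(0)), None, state,
                          opt, MeanTeacherConfig(), rng)


def test_trajectories_are_reproducible():
    lab = (_phantom_images(6, 1, True)[:, None], np.ones(6))
    unl = _phantom_images(6, 2, False)[:, None]
    cfg = MeanTeacherConfig(epochs=1, batch_size=3)
    a = train_mean_teacher(lab, unl, cfg, NET, seed=9)
    b = train_mean_teacher(lab, unl, cfg, NET, seed=9)
    sa, sb = a.student.state_dict(), b.student.state_dict()
    assert all(np.array_equal(sa[k], sb[k]) for k in sa)


def test_partition_threshold_extremes_and_exhaustiveness():
    clf = build_classifier(NET, 0)
    images = _phantom_images(6, 3, True)[:, None]
    every = partition_dataset(clf, images, confidence_threshold=0.0)
    none = partition_dataset(clf, images, confidence_threshold=1.0 + 1e-9)
    assert len(every.effective) == 6 and len(every.difficult) == 0
    assert len(none.effective) == 0 and len(none.difficult) == 6
    mid = partition_dataset(clf, images, confidence_threshold=0.5)
    assert sorted(mid.effective + mid.difficult) == list(range(6))
    assert set(mid.scores) == set(range(6))


def test_partition_recovers_constructed_proportions():
    """With a classifier trained on clearly separable phantom classes and a
    0.5 threshold, a 40/60 easy/hard mix partitions near 40%/60%."""
    lab_x = np.concatenate([_phantom_images(10, 11, True),
                            _phantom_images(10, 12, False)])[:, None]
    lab_y = np.array([1.0] * 10 + [0.0] * 10)
    cfg = MeanTeacherConfig(epochs=8, lr=3e-3, batch_size=10,
                            consistency_weight=0.0)
    state = train_mean_teacher((lab_x, lab_y), np.empty(0), cfg, NET, seed=4)
    mix = np.concatenate([_phantom_images(20, 13, True),
                          _phantom_images(30, 14, False)])[:, None]
    part = partition_dataset(state.student, mix, confidence_threshold=0.5)
    eff, dif = part.proportions
    assert eff == pytest.approx(0.4, abs=0.1)
    assert dif == pytest.approx(0.6, abs=0.1)
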