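"""Distillation losses (hand-checked values), teacher/student training
contracts, and candidate classification."""

import numpy as np
import pandas as pd
import pytest

from cmbkit import nn
from cmbkit.detector import TrainSchedule
from cmbkit.distill import (
    KDLossParams,
    StudentConfig,
    StudentModel,
    TeacherConfig,
    classify_candidates,
    kd_loss,
    softmax_with_temperature,
    total_student_loss,
    train_student,
    train_teacher,
)
from cmbkit.errors import ContractError, ParameterError
from cmbkit.sampling import Candidate, Patch, PatchSet
from tests.conftest import make_ball

TEACHER = TeacherConfig(base_width=2, projection_channels=2,
                        classifier_width=4, fc_sizes=(16, 8, 4),
                        patch_size=16, init_sigma=None, seed=0)
STUDENT = StudentConfig(base_width=2, projection_channels=2,
                        classifier_width=2, fc_sizes=(8, 4, 4),
                        patch_size=16, init_sigma=None, seed=1)


class TestSoftmaxTemperature:
    def test_symmetric_logits(self):
        for tau in (1.0, 2.0, 4.0):
            np.testing.assert_allclose(
                softmax_with_temperature(np.array([0.0, 0.0]), tau), [0.5, 0.5]
            )

    def test_hand_values_tau1(self):
        p = softmax_with_temperature(np.array([2.0, 0.0]), 1.0)
        np.testing.assert_allclose(p, [0.8808, 0.1192], atol=1e-4)

    def test_hand_values_tau4_softer(self):
        p1 = softmax_with_temperature(np.array([2.0, 0.0]), 1.0)
        p4 = softmax_with_temperature(np.array([2.0, 0.0]), 4.0)
        np.testing.assert_allclose(p4, [0.6225, 0.3775], atol=1e-4)

        def entropy(p):
            return -(p * np.log(p)).sum()

        assert entropy(p4) > entropy(p1)

    def test_invalid_temperature(self):
        with pytest.raises(ParameterError):
            softmax_with_temperature(np.array([1.0, 0.0]), 0.0)


class TestKDLoss:
    def test_identity_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            z = rng.standard_normal(2)
            assert kd_loss(z, z, tau=4.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        """KL((.5,.5) || (.75,.25)) = .5 ln(.5/.75) + .5 ln(.5/.25) ~ 0.1438."""
        val = kd_loss(np.array([0.0, 0.0]), np.array([np.log(3.0), 0.0]), 1.0)
        assert val == pytest.approx(0.14384, abs=1e-4)

    def test_softening_shrinks_divergence(self):
        z_s = np.array([0.5, -0.5])
        z_t = np.array([2.0, -1.0])
        assert kd_loss(z_s, z_t, 4.0) < kd_loss(z_s, z_t, 1.0)

    def test_gibbs_nonnegative_random_pairs(self):
        rng = np.random.default_rng(1)
        z_s = rng.standard_normal((1000, 2)) * 3
        z_t = rng.standard_normal((1000, 2)) * 3
        for row_s, row_t in zip(z_s, z_t):
            assert kd_loss(row_s, row_t, 4.0) >= 0.0


class TestTotalStudentLoss:
    def test_beta_zero_reduces_to_alpha_ce(self):
        rng = np.random.default_rng(2)
        z_s = rng.standard_normal((16, 2))
        z_t = rng.standard_normal((16, 2))
        y = rng.integers(0, 2, 16)
        total = total_student_loss(z_s, y, z_t, KDLossParams(tau=4, alpha=0.7,
                                                             beta=0.0))
        p = nn.softmax(z_s, axis=-1)
        ce = -np.log(p[np.arange(16), y]).mean()
        assert total == pytest.approx(0.7 * ce, abs=1e-9)

    def test_perfect_student_zero(self):
        z = np.array([[10.0, -10.0]])
        assert total_student_loss(z, np.array([0]), z,
                                  KDLossParams()) == pytest.approx(0, abs=1e-8)

    def test_composed_hand_value(self):
        """0.4 * (-ln 0.5) + 0.6 * 0.14384 ~ 0.3635."""
        val = total_student_loss(
            np.array([0.0, 0.0]), np.array([0]), np.array([np.log(3.0), 0.0]),
            KDLossParams(tau=1.0, alpha=0.4, beta=0.6),
        )
        assert val == pytest.approx(0.3635, abs=2e-4)

    def test_monotone_in_weights(self):
        z_s = np.array([[1.0, -1.0]])
        z_t = np.array([[-2.0, 2.0]])
        y = np.array([1])
        lo = total_student_loss(z_s, y, z_t, KDLossParams(tau=2, alpha=0.2,
                                                          beta=0.3))
        hi = total_student_loss(z_s, y, z_t, KDLossParams(tau=2, alpha=0.4,
                                                          beta=0.6))
        assert hi > lo

    def test_params_validated(self):
        with pytest.raises(ParameterError):
            KDLossParams(tau=0.5)
        with pytest.raises(ParameterError):
            KDLossParams(alpha=-0.1)


def _teacher_patches(n, size=16, seed=0):
    """Separable toy set: CMB patches contain a bright ball in both channels."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        img = rng.random((size, size, size, 2)).astype(np.float32) * 0.2
        seg = np.zeros((size, size, size), np.uint8)
        cls = i % 2
        if cls:
            lo = min(5, size // 2 - 1)
            c = tuple(rng.integers(lo, size - lo, 3))
            seg = make_ball((size, size, size), c, 2.5)
            img[..., 0] += 0.7 * seg
            img[..., 1] += 0.9 * seg
        out.append(Patch(image=img, seg_label=seg, class_label=cls))
    return PatchSet(out)


SCHED = TrainSchedule(lr0=1e-2, lr_step_epochs=100, max_epochs=5, patience=6,
                      seed=0)


@pytest.fixture(scope="module")
def toy_teacher():
    return train_teacher(_teacher_patches(16), _teacher_patches(6, seed=5),
                         SCHED, TEACHER)


class TestTrainTeacher:
    def test_both_arm_losses_decrease(self, toy_teacher):
        log = toy_teacher.log
        assert log["train_seg_loss"].iloc[-1] < log["train_seg_loss"].iloc[0]
        assert log["train_cls_loss"].iloc[-1] < log["train_cls_loss"].iloc[0]

    def test_patch_size_contract(self):
        with pytest.raises(ContractError):
            train_teacher(_teacher_patches(4, size=8),
                          _teacher_patches(2, size=8), SCHED, TEACHER)

    def test_empty_set_rejected(self):
        with pytest.raises(ContractError):
            train_teacher(PatchSet([]), _teacher_patches(2), SCHED, TEACHER)


class TestTrainStudent:
    def test_distillation_runs_and_student_smaller(self, toy_teacher):
        student = train_student(
            _teacher_patches(12, seed=2), _teacher_patches(4, seed=3),
            toy_teacher, KDLossParams(), SCHED, STUDENT,
        )
        assert student.trained
        assert nn.n_parameters(student.net) < nn.n_parameters(toy_teacher.net)
        assert student.log["train_loss"].iloc[-1] < student.log[
            "train_loss"].iloc[0]

    def test_beta_zero_is_plain_classifier(self, toy_teacher):
        """With alpha=1, beta=0 the teacher's outputs cannot influence
        training: two different teachers yield identical students."""
        other_teacher = train_teacher(
            _teacher_patches(10, seed=7), _teacher_patches(4, seed=8),
            SCHED, TEACHER,
        )
        kw = dict(
            train_patches=_teacher_patches(8, seed=4),
            val_patches=_teacher_patches(4, seed=6),
            params=KDLossParams(alpha=1.0, beta=0.0),
            schedule=SCHED,
            config=STUDENT,
        )
        a = train_student(teacher=toy_teacher, **kw)
        b = train_student(teacher=other_teacher, **kw)
        for pa, pb in zip(a.net.params(), b.net.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_empty_candidates_rejected(self, toy_teacher):
        with pytest.raises(ContractError):
            train_student(PatchSet([]), PatchSet([]), toy_teacher,
                          KDLossParams(), SCHED, STUDENT)


class TestClassifyCandidates:
    def _setup(self, toy_teacher):
        student = train_student(
            _teacher_patches(8, seed=10), _teacher_patches(4, seed=11),
            toy_teacher, KDLossParams(), SCHED, STUDENT,
        )
        shape = (32, 32, 32)
        rng = np.random.default_rng(3)
        cands = [
            Candidate(index=0, coords=np.argwhere(
                make_ball(shape, (10, 10, 10), 2.0)), centroid=(10, 10, 10),
                mean_prob=0.9),
            Candidate(index=1, coords=np.argwhere(
                make_ball(shape, (22, 22, 22), 2.0)), centroid=(22, 22, 22),
                mean_prob=0.8),
        ]
        patches = PatchSet([
            Patch(image=rng.random((16, 16, 16, 2)).astype(np.float32),
                  candidate_index=c.index, center=tuple(map(int, c.centroid)))
            for c in cands
        ])
        return student, patches, cands, shape

    def test_threshold_zero_retains_all(self, toy_teacher):
        student, patches, cands, shape = self._setup(toy_teacher)
        records, retained = classify_candidates(student, patches, cands, 0.0,
                                                shape)
        assert records["retained"].all()
        union = np.zeros(shape, np.uint8)
        for c in cands:
            union[tuple(c.coords.T)] = 1
        np.testing.assert_array_equal(retained, union)

    def test_threshold_one_retains_nothing(self, toy_teacher):
        student, patches, cands, shape = self._setup(toy_teacher)
        records, retained = classify_candidates(student, patches, cands, 1.0,
                                                shape)
        assert not records["retained"].any()
        assert retained.sum() == 0

    def test_empty_patchset_ok(self, toy_teacher):
        student, _, _, shape = self._setup(toy_teacher)
        records, retained = classify_candidates(student, PatchSet([]), [], 0.5,
                                                shape)
        assert isinstance(records, pd.DataFrame) and len(records) == 0
        assert retained.sum() == 0
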