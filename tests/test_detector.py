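"""Detection loss identities, training-loop contracts, whole-image inference."""

import numpy as np
import pytest

from cmbkit import nn
from cmbkit.detector import (
    DetectorConfig,
    DetectorModel,
    TrainSchedule,
    detection_loss,
    load_detector,
    predict_candidates,
    save_checkpoint,
    train_detector,
)
from cmbkit.errors import ContractError
from cmbkit.frst import FRSTMap
from cmbkit.preprocess import PreprocessedVolume
from cmbkit.sampling import Patch, PatchSet
from tests.conftest import make_ball

TINY = DetectorConfig(base_width=2, projection_channels=2, init_sigma=None,
                      seed=0)


def _patches(n, size=16, seed=0, with_ball=True):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        img = rng.random((size, size, size, 2)).astype(np.float32) * 0.2
        seg = np.zeros((size, size, size), np.uint8)
        if with_ball:
            c = tuple(rng.integers(5, size - 5, 3))
            ball = make_ball((size, size, size), c, 2.5)
            seg = ball
            img[..., 0] += 0.7 * ball
            img[..., 1] += 0.9 * ball
        out.append(Patch(image=img, seg_label=seg))
    return PatchSet(out)


class TestDetectionLoss:
    def test_perfect_prediction_zero_loss(self):
        t = np.zeros((6, 6, 6), np.int64)
        t[2, 2, 2] = 1
        pred = np.stack([1.0 - t, t.astype(float)], axis=-1)
        assert detection_loss(pred, t) == pytest.approx(0.0, abs=1e-9)

    def test_dice_term_hand_example(self):
        """Single-voxel target, CMB-prob 0.5 there and 0 elsewhere:
        soft Dice loss = 1 - (2*0.5+1)/(0.5+1+1) = 0.2."""
        t = np.zeros((5, 5, 5), np.int64)
        t[2, 2, 2] = 1
        p1 = np.zeros((5, 5, 5))
        p1[2, 2, 2] = 0.5
        pred = np.stack([1.0 - p1, p1], axis=-1)
        ce = 10.0 * -np.log(0.5) / t.size  # only the target voxel contributes
        assert detection_loss(pred, t) == pytest.approx(ce + 0.2, abs=1e-9)

    def test_false_positive_raises_loss(self):
        t = np.zeros((6, 6, 6), np.int64)
        base = np.stack([np.ones((6, 6, 6)), np.zeros((6, 6, 6))], axis=-1)
        flipped = base.copy()
        flipped[3, 3, 3] = [1e-12, 1.0 - 1e-12]
        assert detection_loss(flipped, t) > detection_loss(base, t)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            detection_loss(np.zeros((4, 4, 4, 2)), np.zeros((4, 4, 5)))

    def test_gradient_path_matches_value(self):
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((2, 4, 4, 4, 2))
        t = (rng.random((2, 4, 4, 4)) > 0.8).astype(np.int64)
        loss, _ = nn.weighted_ce_dice_loss(logits, t)
        probs = nn.softmax(logits, axis=-1)
        assert loss == pytest.approx(detection_loss(probs, t), rel=1e-9)


class TestTrainDetector:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ContractError):
            train_detector(PatchSet([]), _patches(1), TrainSchedule(), TINY)

    def test_fixed_seed_reproducible(self):
        sched = TrainSchedule(max_epochs=2, patience=5, seed=3)
        a = train_detector(_patches(6), _patches(2, seed=9), sched, TINY)
        b = train_detector(_patches(6), _patches(2, seed=9), sched, TINY)
        assert np.allclose(a.log["train_loss"], b.log["train_loss"])
        for pa, pb in zip(a.net.params(), b.net.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_early_stop_after_plateau(self):
        """With lr=0 nothing improves, so training stops patience+1 epochs in."""
        sched = TrainSchedule(lr0=0.0, lr_min=0.0, max_epochs=50, patience=2,
                              seed=0)
        model = train_detector(_patches(4), _patches(2, seed=9), sched, TINY)
        assert len(model.log) == 3

    def test_lr_schedule_sequence(self):
        sched = TrainSchedule()
        lrs = [sched.lr_at(e) for e in range(10)]
        assert lrs == pytest.approx(
            [1e-3, 1e-3, 1e-4, 1e-4, 1e-5, 1e-5, 1e-6, 1e-6, 1e-6, 1e-6]
        )

    def test_overfit_one_batch_sanity(self):
        """Loss on a single repeated batch drops below 0.05 within 200 steps."""
        ps = _patches(8, size=16, seed=1)
        x = ps.stack_images()
        y = ps.stack_seg()
        net = TINY.build()
        opt = nn.Adam(net.params(), lr=2e-2)
        loss = None
        for it in range(200):
            logits = net.forward(x, train=True)
            loss, dl = nn.weighted_ce_dice_loss(logits, y)
            if loss < 0.05:
                break
            opt.zero_grad()
            net.backward(dl)
            opt.step()
        assert loss < 0.05


class TestPredictCandidates:
    def _inputs(self, shape=(30, 26, 26)):
        rng = np.random.default_rng(2)
        pvol = PreprocessedVolume(
            data=rng.random(shape).astype(np.float32), spacing=(1, 1, 1),
            modality="SWI",
        )
        fr = FRSTMap(data=rng.random(shape).astype(np.float32),
                     radii_used=(2, 3))
        return pvol, fr

    def test_untrained_model_rejected(self):
        model = DetectorModel(net=TINY.build(), config=TINY, trained=False)
        pvol, fr = self._inputs()
        with pytest.raises(ContractError):
            predict_candidates(pvol, fr, model)

    def test_probabilities_in_unit_range_any_shape(self):
        model = DetectorModel(net=TINY.build(), config=TINY, trained=True)
        pvol, fr = self._inputs((30, 26, 26))  # not multiples of 4
        cm = predict_candidates(pvol, fr, model)
        assert cm.shape == (30, 26, 26)
        assert cm.data.min() >= 0 and cm.data.max() <= 1

    def test_fully_convolutional_consistency(self):
        """Sub-volume prediction equals the whole-volume crop away from the
        receptive field (radius ~23 voxels for this two-level architecture)."""
        model = DetectorModel(net=TINY.build(), config=TINY, trained=True)
        rng = np.random.default_rng(4)
        shape = (72, 48, 48)
        data = rng.random(shape).astype(np.float32)
        fr = rng.random(shape).astype(np.float32)
        pv = PreprocessedVolume(data=data, spacing=(1, 1, 1), modality="SWI")
        whole = predict_candidates(pv, FRSTMap(fr, (2,)), model).data
        off = (8, 0, 0)
        sub = tuple(slice(o, o + 48) for o in off)
        pv_sub = PreprocessedVolume(data=data[sub], spacing=(1, 1, 1),
                                    modality="SWI")
        part = predict_candidates(pv_sub, FRSTMap(fr[sub], (2,)), model).data
        m = 24
        np.testing.assert_allclose(
            whole[sub][m:-m or None, m:-m or None, m:-m or None],
            part[m:-m or None, m:-m or None, m:-m or None],
            atol=1e-5,
        )


def test_checkpoint_roundtrip(tmp_path):
    sched = TrainSchedule(max_epochs=1, patience=2, seed=0)
    model = train_detector(_patches(4), _patches(2, seed=5), sched, TINY)
    save_checkpoint(model, tmp_path / "det.npz")
    back = load_detector(tmp_path / "det.npz")
    pvol = PreprocessedVolume(
        data=np.random.default_rng(0).random((16, 16, 16)).astype(np.float32),
        spacing=(1, 1, 1), modality="SWI",
    )
    fr = FRSTMap(np.zeros((16, 16, 16), np.float32), (2,))
    np.testing.assert_array_equal(
        predict_candidates(pvol, fr, model).data,
        predict_candidates(pvol, fr, back).data,
    )
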