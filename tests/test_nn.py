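"""Backprop engine: numeric gradient checks and optimiser/layer contracts."""

import numpy as np
import pytest

from cmbkit import nn


def numeric_grad_param(loss_fn, param, indices, eps=1e-6):
    out = []
    flat = param.value.ravel()
    for j in indices:
        orig = flat[j]
        flat[j] = orig + eps
        fp = loss_fn()
        flat[j] = orig - eps
        fm = loss_fn()
        flat[j] = orig
        out.append((fp - fm) / (2 * eps))
    return np.array(out)


@pytest.mark.parametrize("k", [1, 3])
def test_conv3d_gradients_match_numeric(k):
    rng = np.random.default_rng(0)
    conv = nn.Conv3d(3, 2, k=k, rng=rng, dtype=np.float64)
    x = rng.standard_normal((2, 4, 4, 4, 3))
    w = rng.standard_normal((2, 4, 4, 4, 2))  # random projection for scalar loss

    def loss():
        return float((conv.forward(x) * w).sum())

    y = conv.forward(x)
    conv.W.grad[...] = 0
    conv.b.grad[...] = 0
    dx = conv.backward(w)
    idx = rng.choice(conv.W.value.size, 6, replace=False)
    np.testing.assert_allclose(
        conv.W.grad.ravel()[idx], numeric_grad_param(loss, conv.W, idx), atol=1e-6
    )
    j = rng.choice(x.size, 6, replace=False)
    num_dx = []
    for jj in j:
        orig = x.ravel()[jj]
        x.ravel()[jj] = orig + 1e-6
        fp = loss()
        x.ravel()[jj] = orig - 1e-6
        fm = loss()
        x.ravel()[jj] = orig
        num_dx.append((fp - fm) / 2e-6)
    np.testing.assert_allclose(dx.ravel()[j], num_dx, atol=1e-6)


def test_unet_end_to_end_gradients():
    rng = np.random.default_rng(1)
    net = nn.UNet3D(cin=2, proj=2, base=2, rng=rng, dtype=np.float64)
    x = rng.standard_normal((2, 8, 8, 8, 2))
    t = (rng.random((2, 8, 8, 8)) > 0.85).astype(np.int64)

    def loss():
        return nn.weighted_ce_dice_loss(net.forward(x), t)[0]

    logits = net.forward(x)
    _, dl = nn.weighted_ce_dice_loss(logits, t)
    for p in net.params():
        p.grad[...] = 0
    net.backward(dl)
    for p in (net.params()[0], net.params()[7], net.params()[-1]):
        idx = rng.choice(p.value.size, min(4, p.value.size), replace=False)
        np.testing.assert_allclose(
            p.grad.ravel()[idx], numeric_grad_param(loss, p, idx),
            rtol=1e-4, atol=1e-7,
        )


def test_teacher_and_student_gradients():
    rng = np.random.default_rng(2)
    teacher = nn.TeacherNet(cin=2, proj=2, base=2, cls_width=4,
                            fc_sizes=(16, 8, 4), patch_size=8, rng=rng,
                            dtype=np.float64)
    x = rng.standard_normal((3, 8, 8, 8, 2))
    t = (rng.random((3, 8, 8, 8)) > 0.9).astype(np.int64)
    y = np.array([0, 1, 1])

    def tloss():
        s, c = teacher.forward(x)
        return nn.weighted_ce_dice_loss(s, t)[0] + nn.ce_loss(c, y)[0]

    s, c = teacher.forward(x)
    _, dseg = nn.weighted_ce_dice_loss(s, t)
    _, dcls = nn.ce_loss(c, y)
    for p in teacher.params():
        p.grad[...] = 0
    teacher.backward(dseg, dcls)
    for p in (teacher.params()[0], teacher.params()[-2]):
        idx = rng.choice(p.value.size, min(4, p.value.size), replace=False)
        np.testing.assert_allclose(
            p.grad.ravel()[idx], numeric_grad_param(tloss, p, idx),
            rtol=1e-4, atol=1e-7,
        )

    student = nn.StudentNet(cin=2, proj=2, base=2, cls_width=2,
                            fc_sizes=(8, 4, 4), patch_size=8, rng=rng,
                            dtype=np.float64)
    z_t = rng.standard_normal((3, 2))

    def sloss():
        return nn.total_student_loss_value(
            student.forward(x), y, z_t, 4.0, 0.4, 0.6
        )

    z = student.forward(x)
    _, dz = nn.total_student_loss_value(z, y, z_t, 4.0, 0.4, 0.6, with_grad=True)
    for p in student.params():
        p.grad[...] = 0
    student.backward(dz)
    p = student.params()[0]
    idx = rng.choice(p.value.size, 4, replace=False)
    np.testing.assert_allclose(
        p.grad.ravel()[idx], numeric_grad_param(sloss, p, idx),
        rtol=1e-4, atol=1e-7,
    )


def test_maxpool_routes_gradient_to_argmax():
    rng = np.random.default_rng(3)
    pool = nn.MaxPool3d()
    x = rng.standard_normal((1, 4, 4, 4, 2))
    y = pool.forward(x)
    dy = np.ones_like(y)
    dx = pool.backward(dy)
    assert dx.sum() == y.size  # one unit of gradient per pooled window
    assert np.all((dx == 0) | (dx == 1))
    np.testing.assert_array_equal((dx * x).sum(axis=(1, 2, 3)),
                                  y.sum(axis=(1, 2, 3)))


def test_upsample_linear_and_adjoint():
    rng = np.random.default_rng(4)
    up = nn.Upsample3d()
    x = rng.standard_normal((1, 2, 2, 2, 3))
    y = up.forward(x)
    assert y.shape == (1, 4, 4, 4, 3)
    # constant fields upsample exactly (partition of unity)
    const = np.full((1, 3, 3, 3, 1), 0.7)
    np.testing.assert_allclose(up.forward(const), 0.7)
    dy = rng.standard_normal(y.shape)
    up.forward(x)
    dx = up.backward(dy)
    # adjoint identity: <up(x), dy> == <x, up^T(dy)>
    assert np.allclose((y * dy).sum(), (x * dx).sum())


def test_truncated_normal_bounds_and_bias_init():
    rng = np.random.default_rng(5)
    w = nn.truncated_normal(rng, (1000,), sigma=0.05)
    assert np.abs(w).max() <= 0.1 + 1e-7  # 2 sigma truncation
    conv = nn.Conv3d(2, 2, rng=rng)
    assert np.all(conv.b.value == np.float32(0.1))


def test_adam_reduces_quadratic():
    rng = np.random.default_rng(6)
    p = nn.Param(rng.standard_normal(10).astype(np.float64))
    opt = nn.Adam([p], lr=0.1)
    for _ in range(100):
        opt.zero_grad()
        p.grad += 2 * p.value
        opt.step()
    assert np.abs(p.value).max() < 0.05


def test_dropout_train_vs_eval():
    rng = np.random.default_rng(7)
    drop = nn.Dropout(0.5, np.random.default_rng(0))
    x = np.ones((4, 100))
    y_eval = drop.forward(x, train=False)
    np.testing.assert_array_equal(y_eval, x)
    y_train = drop.forward(x, train=True)
    assert set(np.unique(y_train)) <= {0.0, 2.0}  # scaled by 1/(1-p)


def test_state_roundtrip_and_param_counts():
    rng = np.random.default_rng(8)
    a = nn.StudentNet(cin=2, proj=2, base=2, cls_width=2, fc_sizes=(8, 4, 4),
                      patch_size=8, rng=rng)
    b = nn.StudentNet(cin=2, proj=2, base=2, cls_width=2, fc_sizes=(8, 4, 4),
                      patch_size=8, rng=np.random.default_rng(99))
    state = nn.get_state(a)
    nn.set_state(b, state)
    x = np.random.default_rng(1).standard_normal((2, 8, 8, 8, 2)).astype(
        np.float32
    )
    np.testing.assert_array_equal(a.forward(x), b.forward(x))
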