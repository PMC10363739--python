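"""A compact CPU backprop engine for the small 3D CNNs used by the pipeline.

The detection and discrimination networks are shallow (two pooling levels,
a handful of convolutions), operate on modest patch sizes (24--48 voxels per
side) and are trained on synthetic data at desk scale, so a full deep-learning
framework is unnecessary: this module implements exactly the layers the
architectures need — 3D convolution (JIT-compiled direct kernels), 2x2x2 max
pooling, trilinear upsampling, fully connected layers, leaky rectifiers,
dropout — with explicit backward passes, truncated-normal initialisation and
an Adam optimiser.

Array layout is channels-last: ``(N, D, H, W, C)``.
"""

from __future__ import annotations

import numba
import numpy as np

from .errors import ContractError, ParameterError

__all__ = [
    "Param",
    "Adam",
    "Conv3d",
    "MaxPool3d",
    "Upsample3d",
    "ReLU",
    "Dropout",
    "Linear",
    "Flatten",
    "DoubleConv",
    "Encoder",
    "Decoder",
    "UNet3D",
    "ClassifierHead",
    "TeacherNet",
    "StudentNet",
    "softmax",
    "softmax_with_temperature",
    "weighted_ce_dice_loss",
    "ce_loss",
    "kd_loss_value",
    "total_student_loss_value",
    "n_parameters",
]


# ---------------------------------------------------------------------------
# parameters, init, optimiser
# ---------------------------------------------------------------------------


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def truncated_normal(rng, shape, sigma=0.05, nsigma=2.0, dtype=np.float32):
    """Normal(0, sigma) resampled until all values lie within nsigma*sigma."""
    x = rng.normal(0.0, sigma, size=shape)
    bad = np.abs(x) > nsigma * sigma
    while bad.any():
        x[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
        bad = np.abs(x) > nsigma * sigma
    return x.astype(dtype)


class Adam:
    """Adam optimiser; the epsilon default of 1e-4 matches the training
    recipe the detection networks were published with."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-4):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


@numba.njit(cache=True, fastmath=True)
def _conv3_fwd(xp, w, b, y):  # pragma: no cover - exercised via Conv3d
    # channels-first: xp (N, Ci, D+2, H+2, W+2), w (Co, Ci, 3, 3, 3),
    # y (N, Co, D, H, W); innermost width loop is contiguous for SIMD.
    n_b, co, d, h, wd = y.shape
    ci = xp.shape[1]
    for n in range(n_b):
        for o in range(co):
            for i in range(d):
                for j in range(h):
                    for l in range(wd):
                        y[n, o, i, j, l] = b[o]
                    for q in range(ci):
                        for a in range(3):
                            for bb in range(3):
                                for c in range(3):
                                    wv = w[o, q, a, bb, c]
                                    for l in range(wd):
                                        y[n, o, i, j, l] += (
                                            wv * xp[n, q, i + a, j + bb, l + c]
                                        )


@numba.njit(cache=True, fastmath=True)
def _conv3_bwd_dx(dy, w, dxp):  # pragma: no cover
    n_b, co, d, h, wd = dy.shape
    ci = dxp.shape[1]
    for n in range(n_b):
        for q in range(ci):
            for o in range(co):
                for a in range(3):
                    for bb in range(3):
                        for c in range(3):
                            wv = w[o, q, a, bb, c]
                            for i in range(d):
                                for j in range(h):
                                    for l in range(wd):
                                        dxp[n, q, i + a, j + bb, l + c] += (
                                            wv * dy[n, o, i, j, l]
                                        )


@numba.njit(cache=True, fastmath=True)
def _conv3_bwd_dw(xp, dy, dw):  # pragma: no cover
    n_b, co, d, h, wd = dy.shape
    ci = xp.shape[1]
    acc = np.zeros((3, 3, 3), dtype=np.float64)
    for n in range(n_b):
        for o in range(co):
            for q in range(ci):
                acc[:, :, :] = 0.0
                for i in range(d):
                    for j in range(h):
                        for a in range(3):
                            for bb in range(3):
                                for c in range(3):
                                    s = 0.0
                                    for l in range(wd):
                                        s += (
                                            xp[n, q, i + a, j + bb, l + c]
                                            * dy[n, o, i, j, l]
                                        )
                                    acc[a, bb, c] += s
                for a in range(3):
                    for bb in range(3):
                        for c in range(3):
                            dw[o, q, a, bb, c] += acc[a, bb, c]


def _to_cf(x):
    return np.ascontiguousarray(x.transpose(0, 4, 1, 2, 3))


def _to_cl(x):
    return np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1))


class Conv3d:
    """Same-padding, stride-1 3D convolution (kernel 1 or 3).

    The 3x3x3 path runs fused, JIT-compiled direct-convolution kernels in
    channels-first order — the channel counts here are too narrow for
    GEMM-based im2col to be anything but memory-bound on CPU.  Weights are
    stored as (c_out, c_in, k, k, k).
    """

    def __init__(self, cin, cout, k=3, rng=None, sigma=0.05, bias_init=0.1,
                 dtype=np.float32):
        if k not in (1, 3):
            raise ParameterError("kernel size must be 1 or 3")
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        if sigma is None:  # He-scaled init for reduced-width configurations
            sigma = float(np.sqrt(2.0 / (cin * k**3)))
        self.W = Param(
            truncated_normal(rng, (cout, cin, k, k, k), sigma=sigma, dtype=dtype)
        )
        self.b = Param(np.full((cout,), bias_init, dtype=dtype))
        self._x = None
        self._xp = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        n, d, h, w, _ = x.shape
        if self.k == 1:
            self._x = x
            y = x.reshape(-1, self.cin) @ self.W.value.reshape(
                self.cout, self.cin
            ).T + self.b.value
            return y.reshape(n, d, h, w, self.cout)
        xp = _to_cf(np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0))))
        self._xp = xp
        y = np.empty((n, self.cout, d, h, w), dtype=x.dtype)
        _conv3_fwd(xp, self.W.value, self.b.value, y)
        return _to_cl(y)

    def backward(self, dy):
        if self.k == 1:
            dy_flat = dy.reshape(-1, self.cout)
            self.b.grad += dy_flat.sum(axis=0)
            x = self._x
            self.W.grad += (
                x.reshape(-1, self.cin).T @ dy_flat
            ).T.reshape(self.W.grad.shape)
            dx = dy_flat @ self.W.value.reshape(self.cout, self.cin)
            return dx.reshape(x.shape)
        dy_cf = _to_cf(dy)
        self.b.grad += dy_cf.sum(axis=(0, 2, 3, 4))
        xp = self._xp
        dxp = np.zeros_like(xp)
        _conv3_bwd_dx(dy_cf, self.W.value, dxp)
        _conv3_bwd_dw(xp, dy_cf, self.W.grad)
        n, _, d, h, w = dy_cf.shape
        return _to_cl(dxp[:, :, 1:1 + d, 1:1 + h, 1:1 + w])


class MaxPool3d:
    """2x2x2 max pooling; spatial dims must be even."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def params(self):
        return []

    @staticmethod
    def _windows(x):
        n, d, h, w, c = x.shape
        xr = x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4, 6, 7)
        return xr.reshape(n, d // 2, h // 2, w // 2, 8, c)

    def forward(self, x, train=False):
        if any(s % 2 for s in x.shape[1:4]):
            raise ContractError("pooling input sides must be even")
        self._shape = x.shape
        xr = self._windows(x)
        self._idx = xr.argmax(axis=4)
        return np.take_along_axis(xr, self._idx[:, :, :, :, None, :], axis=4)[
            :, :, :, :, 0, :
        ]

    def backward(self, dy):
        n, d, h, w, c = self._shape
        dxr = np.zeros((n, d // 2, h // 2, w // 2, 8, c), dtype=dy.dtype)
        np.put_along_axis(
            dxr, self._idx[:, :, :, :, None, :], dy[:, :, :, :, None, :], axis=4
        )
        dxr = dxr.reshape(n, d // 2, h // 2, w // 2, 2, 2, 2, c)
        dxr = dxr.transpose(0, 1, 4, 2, 5, 3, 6, 7)
        return dxr.reshape(n, d, h, w, c)


class Upsample3d:
    """Trilinear 2x upsampling (separable; half-voxel aligned grids).

    Each axis applies the interpolation matrix with rows
    out[2i] = 0.25 in[i-1] + 0.75 in[i], out[2i+1] = 0.75 in[i] + 0.25 in[i+1]
    (edge-clamped); the backward pass is the exact adjoint.
    """

    _cache: dict[int, np.ndarray] = {}

    def __init__(self):
        self._in_shape = None

    def params(self):
        return []

    @classmethod
    def _matrix(cls, n: int) -> np.ndarray:
        if n not in cls._cache:
            m = np.zeros((2 * n, n))
            for i in range(n):
                m[2 * i, max(i - 1, 0)] += 0.25
                m[2 * i, i] += 0.75
                m[2 * i + 1, i] += 0.75
                m[2 * i + 1, min(i + 1, n - 1)] += 0.25
            cls._cache[n] = m
        return cls._cache[n]

    @staticmethod
    def _apply(x, mats):
        for axis, m in zip((1, 2, 3), mats):
            x = np.moveaxis(
                np.tensordot(m.astype(x.dtype), x, axes=(1, axis)), 0, axis
            )
        return np.ascontiguousarray(x)

    def forward(self, x, train=False):
        self._in_shape = x.shape
        mats = [self._matrix(n) for n in x.shape[1:4]]
        return self._apply(x, mats)

    def backward(self, dy):
        mats = [self._matrix(n).T for n in self._in_shape[1:4]]
        return self._apply(dy, mats)


class ReLU:
    """Rectifier; ``slope`` sets the negative side (0 = hard ReLU).

    With sparse-foreground segmentation losses a hard rectifier admits an
    all-background attractor in which the whole network goes silent.  Rather
    than leak the rectifier (which measurably blunts the converged detector),
    the training pipeline detects that unmistakable degenerate state and
    restarts from a fresh init.
    """

    slope = 0.0

    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train=False):
        self._mask = np.where(x > 0, x.dtype.type(1), x.dtype.type(self.slope))
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout:
    def __init__(self, p, rng):
        self.p = p
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (
            1.0 - self.p
        )
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Linear:
    def __init__(self, nin, nout, rng=None, sigma=0.05, bias_init=0.1,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        if sigma is None:
            sigma = float(np.sqrt(2.0 / nin))
        self.W = Param(truncated_normal(rng, (nin, nout), sigma=sigma, dtype=dtype))
        self.b = Param(np.full((nout,), bias_init, dtype=dtype))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Flatten:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


# ---------------------------------------------------------------------------
# blocks and networks
# ---------------------------------------------------------------------------


class DoubleConv:
    """conv3 -> ReLU -> conv3 -> ReLU."""

    def __init__(self, cin, cout, rng, sigma=0.05, dtype=np.float32):
        self.c1 = Conv3d(cin, cout, 3, rng, sigma=sigma, dtype=dtype)
        self.r1 = ReLU()
        self.c2 = Conv3d(cout, cout, 3, rng, sigma=sigma, dtype=dtype)
        self.r2 = ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x, train=False):
        return self.r2.forward(
            self.c2.forward(self.r1.forward(self.c1.forward(x, train), train), train),
            train,
        )

    def backward(self, dy):
        return self.c1.backward(
            self.r1.backward(self.c2.backward(self.r2.backward(dy)))
        )


class Encoder:
    """Shared feature extractor: 1x1x1 projection + two pooled conv levels."""

    def __init__(self, cin=2, proj=3, base=64, rng=None, sigma=0.05,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.base = base
        self.proj = Conv3d(cin, proj, 1, rng, sigma=sigma, dtype=dtype)
        self.proj_relu = ReLU()
        self.block1 = DoubleConv(proj, base, rng, sigma=sigma, dtype=dtype)
        self.pool1 = MaxPool3d()
        self.block2 = DoubleConv(base, 2 * base, rng, sigma=sigma, dtype=dtype)
        self.pool2 = MaxPool3d()
        self.block3 = DoubleConv(2 * base, 4 * base, rng, sigma=sigma,
                                 dtype=dtype)

    def params(self):
        return (
            self.proj.params()
            + self.block1.params()
            + self.block2.params()
            + self.block3.params()
        )

    def forward(self, x, train=False):
        h = self.proj_relu.forward(self.proj.forward(x, train), train)
        f1 = self.block1.forward(h, train)
        f2 = self.block2.forward(self.pool1.forward(f1), train)
        f3 = self.block3.forward(self.pool2.forward(f2), train)
        return f1, f2, f3

    def backward(self, df1, df2, df3):
        d = self.pool2.backward(self.block3.backward(df3))
        if df2 is not None:
            d = d + df2
        d = self.pool1.backward(self.block2.backward(d))
        if df1 is not None:
            d = d + df1
        d = self.block1.backward(d)
        return self.proj.backward(self.proj_relu.backward(d))


class Decoder:
    """Mirrored decoder with skip concatenation and a 1x1x1 two-class head."""

    def __init__(self, base=64, n_classes=2, rng=None, sigma=0.05,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.base = base
        self.up1 = Upsample3d()
        self.uc1 = Conv3d(4 * base, 2 * base, 3, rng, sigma=sigma, dtype=dtype)
        self.ur1 = ReLU()
        self.dblock1 = DoubleConv(4 * base, 2 * base, rng, sigma=sigma,
                                  dtype=dtype)
        self.up2 = Upsample3d()
        self.uc2 = Conv3d(2 * base, base, 3, rng, sigma=sigma, dtype=dtype)
        self.ur2 = ReLU()
        self.dblock2 = DoubleConv(2 * base, base, rng, sigma=sigma, dtype=dtype)
        self.head = Conv3d(base, n_classes, 1, rng, sigma=sigma, dtype=dtype)

    def params(self):
        return (
            self.uc1.params()
            + self.dblock1.params()
            + self.uc2.params()
            + self.dblock2.params()
            + self.head.params()
        )

    def forward(self, f1, f2, f3, train=False):
        u = self.ur1.forward(self.uc1.forward(self.up1.forward(f3), train), train)
        h = self.dblock1.forward(np.concatenate([u, f2], axis=-1), train)
        u = self.ur2.forward(self.uc2.forward(self.up2.forward(h), train), train)
        h = self.dblock2.forward(np.concatenate([u, f1], axis=-1), train)
        return self.head.forward(h, train)

    def backward(self, dlogits):
        b = self.base
        d = self.dblock2.backward(self.head.backward(dlogits))
        du, df1 = d[..., :b], d[..., b:]
        d = self.up2.backward(self.uc2.backward(self.ur2.backward(du)))
        d = self.dblock1.backward(d)
        du, df2 = d[..., : 2 * b], d[..., 2 * b:]
        df3 = self.up1.backward(self.uc1.backward(self.ur1.backward(du)))
        return df1, df2, df3


class UNet3D:
    """Shallow two-level encoder-decoder for voxel-wise CMB probabilities."""

    def __init__(self, cin=2, proj=3, base=64, rng=None, sigma=0.05,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.encoder = Encoder(cin, proj, base, rng, sigma=sigma, dtype=dtype)
        self.decoder = Decoder(base, 2, rng, sigma=sigma, dtype=dtype)

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def forward(self, x, train=False):
        f1, f2, f3 = self.encoder.forward(x, train)
        return self.decoder.forward(f1, f2, f3, train)

    def backward(self, dlogits):
        df1, df2, df3 = self.decoder.backward(dlogits)
        return self.encoder.backward(df1, df2, df3)


class ClassifierHead:
    """Patch-level classifier arm: 1x1x1 projection, two 3x3x3 convs + pool,
    then FC layers (defaults 1024/128/32) with dropout before the middle FC,
    ending in two class logits."""

    def __init__(self, cin, width=64, fc_sizes=(1024, 128, 32), patch_size=24,
                 dropout=0.2, rng=None, sigma=0.05, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        side = patch_size // 4  # encoder bottleneck side
        if side % 2:
            raise ParameterError("patch size must be divisible by 8")
        self.proj = Conv3d(cin, width, 1, rng, sigma=sigma, dtype=dtype)
        self.r0 = ReLU()
        self.c1 = Conv3d(width, width, 3, rng, sigma=sigma, dtype=dtype)
        self.r1 = ReLU()
        self.c2 = Conv3d(width, width, 3, rng, sigma=sigma, dtype=dtype)
        self.r2 = ReLU()
        self.pool = MaxPool3d()
        self.flat = Flatten()
        nin = (side // 2) ** 3 * width
        self.fc1 = Linear(nin, fc_sizes[0], rng, sigma=sigma, dtype=dtype)
        self.fr1 = ReLU()
        self.drop = Dropout(dropout, rng)
        self.fc2 = Linear(fc_sizes[0], fc_sizes[1], rng, sigma=sigma,
                          dtype=dtype)
        self.fr2 = ReLU()
        self.fc3 = Linear(fc_sizes[1], fc_sizes[2], rng, sigma=sigma,
                          dtype=dtype)
        self.fr3 = ReLU()
        self.out = Linear(fc_sizes[2], 2, rng, sigma=sigma, dtype=dtype)

    def params(self):
        layers = [self.proj, self.c1, self.c2, self.fc1, self.fc2, self.fc3, self.out]
        return [p for layer in layers for p in layer.params()]

    def forward(self, f3, train=False):
        h = self.r0.forward(self.proj.forward(f3, train), train)
        h = self.r1.forward(self.c1.forward(h, train), train)
        h = self.r2.forward(self.c2.forward(h, train), train)
        h = self.flat.forward(self.pool.forward(h))
        h = self.drop.forward(self.fr1.forward(self.fc1.forward(h, train), train),
                              train)
        h = self.fr2.forward(self.fc2.forward(h, train), train)
        h = self.fr3.forward(self.fc3.forward(h, train), train)
        return self.out.forward(h, train)

    def backward(self, dlogits):
        d = self.out.backward(dlogits)
        d = self.fc3.backward(self.fr3.backward(d))
        d = self.fc2.backward(self.fr2.backward(d))
        d = self.fc1.backward(self.fr1.backward(self.drop.backward(d)))
        d = self.pool.backward(self.flat.backward(d))
        d = self.c2.backward(self.r2.backward(d))
        d = self.c1.backward(self.r1.backward(d))
        return self.proj.backward(self.r0.backward(d))


class TeacherNet:
    """Multi-tasking teacher: shared features T_f, segmentor arm T_s (same
    architecture as the candidate detector) and patch classifier arm T_c."""

    def __init__(self, cin=2, proj=3, base=64, cls_width=64,
                 fc_sizes=(1024, 128, 32), patch_size=24, dropout=0.2,
                 rng=None, sigma=0.05, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.encoder = Encoder(cin, proj, base, rng, sigma=sigma, dtype=dtype)
        self.decoder = Decoder(base, 2, rng, sigma=sigma, dtype=dtype)
        self.classifier = ClassifierHead(
            4 * base, cls_width, fc_sizes, patch_size, dropout, rng,
            sigma=sigma, dtype=dtype
        )
        self.patch_size = patch_size

    def params(self):
        return (
            self.encoder.params() + self.decoder.params() + self.classifier.params()
        )

    def forward(self, x, train=False):
        if x.shape[1] != self.patch_size:
            raise ContractError(
                f"teacher expects {self.patch_size}^3 patches, got side {x.shape[1]}"
            )
        f1, f2, f3 = self.encoder.forward(x, train)
        seg_logits = self.decoder.forward(f1, f2, f3, train)
        cls_logits = self.classifier.forward(f3, train)
        return seg_logits, cls_logits

    def backward(self, dseg, dcls):
        df1, df2, df3 = self.decoder.backward(dseg)
        df3 = df3 + self.classifier.backward(dcls)
        return self.encoder.backward(df1, df2, df3)

    def load_detector_weights(self, unet: UNet3D) -> None:
        """Initialise T_f + T_s from a pretrained candidate detector."""
        for dst, src in zip(
            self.encoder.params() + self.decoder.params(),
            unet.encoder.params() + unet.decoder.params(),
        ):
            if dst.value.shape != src.value.shape:
                raise ContractError("detector/teacher architecture mismatch")
            dst.value[...] = src.value


class StudentNet:
    """Lightweight student: feature extractor + patch classifier only."""

    def __init__(self, cin=2, proj=3, base=32, cls_width=32,
                 fc_sizes=(512, 64, 16), patch_size=24, dropout=0.2,
                 rng=None, sigma=0.05, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.encoder = Encoder(cin, proj, base, rng, sigma=sigma, dtype=dtype)
        self.classifier = ClassifierHead(
            4 * base, cls_width, fc_sizes, patch_size, dropout, rng,
            sigma=sigma, dtype=dtype
        )
        self.patch_size = patch_size

    def params(self):
        return self.encoder.params() + self.classifier.params()

    def forward(self, x, train=False):
        if x.shape[1] != self.patch_size:
            raise ContractError(
                f"student expects {self.patch_size}^3 patches, got side {x.shape[1]}"
            )
        _, _, f3 = self.encoder.forward(x, train)
        return self.classifier.forward(f3, train)

    def backward(self, dcls):
        df3 = self.classifier.backward(dcls)
        return self.encoder.backward(None, None, df3)


def n_parameters(model) -> int:
    return int(sum(p.value.size for p in model.params()))


def get_state(model) -> list[np.ndarray]:
    return [p.value.copy() for p in model.params()]


def set_state(model, state) -> None:
    for p, v in zip(model.params(), state):
        if p.value.shape != v.shape:
            raise ContractError("checkpoint does not match model architecture")
        p.value[...] = v


# ---------------------------------------------------------------------------
# losses (values + analytic gradients w.r.t. logits)
# ---------------------------------------------------------------------------


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_with_temperature(z: np.ndarray, tau: float) -> np.ndarray:
    """Temperature-softened softmax: sigma(z_i, tau) = exp(z_i/tau)/sum_j exp(z_j/tau)."""
    if tau <= 0:
        raise ParameterError("temperature must be > 0")
    z = np.asarray(z, dtype=np.float64)
    return softmax(z / tau, axis=-1)


def weighted_ce_dice_loss(
    logits: np.ndarray, target: np.ndarray, cmb_weight: float = 10.0,
    eps_smooth: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted cross-entropy + soft Dice loss on the CMB channel.

    CE weights CMB voxels by ``cmb_weight`` and is averaged over voxels; the
    soft Dice loss is ``1 - (2*sum(p*g)+eps)/(sum(p)+sum(g)+eps)`` computed on
    the CMB-probability channel over the whole batch.  Returns the loss and
    its gradient with respect to the logits.
    """
    if logits.shape[:-1] != target.shape:
        raise ContractError(
            f"prediction grid {logits.shape[:-1]} does not match target "
            f"{target.shape}"
        )
    p = softmax(logits.astype(np.float64), axis=-1)
    t = target.astype(np.float64)
    n_vox = t.size
    w = 1.0 + (cmb_weight - 1.0) * t
    p1 = p[..., 1]
    p_true = np.clip(np.where(t > 0, p1, p[..., 0]), 1e-12, None)
    ce = float((w * -np.log(p_true)).sum() / n_vox)
    onehot = np.stack([1.0 - t, t], axis=-1)
    dce = w[..., None] * (p - onehot) / n_vox

    s_pg = float((p1 * t).sum())
    s_p = float(p1.sum())
    s_g = float(t.sum())
    denom = s_p + s_g + eps_smooth
    dice_loss = 1.0 - (2.0 * s_pg + eps_smooth) / denom
    ddice_dp1 = -(2.0 * t * denom - (2.0 * s_pg + eps_smooth)) / denom**2
    # chain through softmax: dz_k = p_k * (g_k - sum_j g_j p_j), g = (0, ddice_dp1)
    gp = ddice_dp1 * p1
    ddice = np.empty_like(p)
    ddice[..., 0] = p[..., 0] * (-gp)
    ddice[..., 1] = p1 * (ddice_dp1 - gp)
    return ce + dice_loss, (dce + ddice).astype(logits.dtype)


def ce_loss(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean 2-class cross-entropy on patch labels; returns (loss, dlogits)."""
    p = softmax(logits.astype(np.float64), axis=-1)
    n = logits.shape[0]
    idx = np.arange(n)
    loss = float(-np.log(np.clip(p[idx, labels], 1e-12, None)).mean())
    onehot = np.zeros_like(p)
    onehot[idx, labels] = 1.0
    return loss, ((p - onehot) / n).astype(logits.dtype)


def kd_loss_value(
    z_s: np.ndarray, z_t: np.ndarray, tau: float, with_grad: bool = False
):
    """KL(sigma(z_S, tau) || sigma(z_Tc, tau)), averaged over the batch.

    The student's softened distribution is the first KL argument.  The
    optional gradient is with respect to the student logits.
    """
    z_s = np.atleast_2d(np.asarray(z_s, dtype=np.float64))
    z_t = np.atleast_2d(np.asarray(z_t, dtype=np.float64))
    if z_s.shape != z_t.shape:
        raise ContractError("student/teacher logits must have the same shape")
    q = softmax_with_temperature(z_s, tau)
    r = softmax_with_temperature(z_t, tau)
    logratio = np.log(np.clip(q, 1e-12, None)) - np.log(np.clip(r, 1e-12, None))
    kl_per = (q * logratio).sum(axis=-1)
    loss = float(kl_per.mean())
    if not with_grad:
        return loss
    n = z_s.shape[0]
    dz = q * (logratio - kl_per[..., None]) / (tau * n)
    return loss, dz


def total_student_loss_value(
    z_s: np.ndarray,
    y_s: np.ndarray,
    z_t: np.ndarray,
    tau: float,
    alpha: float,
    beta: float,
    with_grad: bool = False,
):
    """alpha * CE(y_S, sigma(z_S, tau=1)) + beta * KL(sigma(z_S,tau), sigma(z_Tc,tau))."""
    z_s2 = np.atleast_2d(np.asarray(z_s, dtype=np.float64))
    y = np.atleast_1d(np.asarray(y_s, dtype=np.int64))
    ce, dce = ce_loss(z_s2, y)
    kd, dkd = kd_loss_value(z_s2, z_t, tau, with_grad=True)
    loss = float(alpha * ce + beta * kd)
    if not with_grad:
        return loss
    return loss, (alpha * dce + beta * dkd)
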