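"""Initial CMB candidate detection: a shallow 3D encoder-decoder.

The detector is a trimmed U-Net with two pooling levels: a 1x1x1 projection
to three channels, 3x3x3 convolutions starting at a configurable base width
(64 by default), 2x2x2 max pooling/upsampling, skip concatenation and a
1x1x1 two-class softmax head.  It is trained on 48-voxel patches with a
combination of cross-entropy (CMB voxels upweighted 10x) and soft Dice loss,
and applied fully convolutionally to whole volumes at test time to produce
the candidate probability map P_Cdet.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .errors import ContractError
from .frst import FRSTMap
from .imaging import BrainMask
from .preprocess import PreprocessedVolume
from .sampling import PatchSet

__all__ = [
    "DetectorConfig",
    "TrainSchedule",
    "CandidateMap",
    "DetectorModel",
    "detection_loss",
    "train_detector",
    "predict_candidates",
    "save_checkpoint",
    "load_detector",
]


@dataclass
class DetectorConfig:
    """Architecture of the shallow encoder-decoder (two pooling levels)."""

    in_channels: int = 2
    projection_channels: int = 3
    base_width: int = 64
    init_sigma: float | None = 0.05  # None -> He-scaled truncated normal
    seed: int = 0

    def build(self, dtype=np.float32) -> nn.UNet3D:
        rng = np.random.default_rng(self.seed)
        return nn.UNet3D(
            cin=self.in_channels,
            proj=self.projection_channels,
            base=self.base_width,
            rng=rng,
            sigma=self.init_sigma,
            dtype=dtype,
        )


@dataclass
class TrainSchedule:
    """Optimiser schedule: Adam(eps=1e-4), batch 8, lr 1e-3 decayed x0.1
    every 2 epochs until 1e-6, up to 100 epochs, early-stop patience 20."""

    lr0: float = 1e-3
    lr_decay: float = 0.1
    lr_step_epochs: int = 2
    lr_min: float = 1e-6
    warmup_epochs: int = 0  # epochs at lr0/10 before the schedule proper
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 20
    adam_eps: float = 1e-4
    seed: int = 0

    def lr_at(self, epoch: int) -> float:
        if epoch < self.warmup_epochs:
            return self.lr0 * 0.1
        epoch = epoch - self.warmup_epochs
        return max(self.lr0 * self.lr_decay ** (epoch // self.lr_step_epochs),
                   self.lr_min)


@dataclass
class CandidateMap:
    """Voxel-wise CMB probability map P_Cdet aligned to its source volume."""

    data: np.ndarray
    threshold_used: float | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class DetectorModel:
    net: nn.UNet3D
    config: DetectorConfig
    trained: bool = False
    log: pd.DataFrame | None = None


def detection_loss(
    pred: np.ndarray, target: np.ndarray, cmb_weight: float = 10.0
) -> float:
    """Weighted CE + soft Dice loss from per-voxel class *probabilities*.

    ``pred`` holds the 2-class probabilities in the last axis (summing to 1
    voxel-wise); CMB voxels are upweighted ``cmb_weight``-fold in the CE term
    and the soft Dice loss uses smoothing epsilon 1.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target)
    if pred.shape[:-1] != target.shape or pred.shape[-1] != 2:
        raise ContractError("prediction/target shape mismatch")
    t = target.astype(np.float64)
    w = 1.0 + (cmb_weight - 1.0) * t
    p_true = np.clip(np.where(t > 0, pred[..., 1], pred[..., 0]), 1e-12, None)
    ce = float((w * -np.log(p_true)).sum() / t.size)
    p1 = pred[..., 1]
    eps = 1.0
    dice = 1.0 - (2.0 * float((p1 * t).sum()) + eps) / (
        float(p1.sum()) + float(t.sum()) + eps
    )
    return ce + dice


def _epoch_batches(n: int, batch_size: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def _eval_detection_loss(net, x, y, batch_size, cmb_weight):
    total, count = 0.0, 0
    for i in range(0, len(x), batch_size):
        logits = net.forward(x[i:i + batch_size], train=False)
        loss, _ = nn.weighted_ce_dice_loss(logits, y[i:i + batch_size],
                                           cmb_weight=cmb_weight)
        total += loss * len(x[i:i + batch_size])
        count += len(x[i:i + batch_size])
    return total / max(count, 1)


def train_detector(
    train_patches: PatchSet,
    val_patches: PatchSet,
    schedule: TrainSchedule,
    config: DetectorConfig,
    cmb_weight: float = 10.0,
) -> DetectorModel:
    """Train the candidate detector; returns the best-validation-loss weights
    together with a per-epoch log (train/val loss, learning rate)."""
    if len(train_patches) == 0:
        raise ContractError("empty training patch set")
    if len(val_patches) == 0:
        raise ContractError("empty validation patch set")
    net = config.build()
    x_tr = train_patches.stack_images()
    y_tr = train_patches.stack_seg()
    x_va = val_patches.stack_images()
    y_va = val_patches.stack_seg()
    opt = nn.Adam(net.params(), lr=schedule.lr0, eps=schedule.adam_eps)
    rng = np.random.default_rng(schedule.seed)
    best_val, best_state, best_epoch = np.inf, nn.get_state(net), -1
    rows = []
    for epoch in range(schedule.max_epochs):
        opt.lr = schedule.lr_at(epoch)
        tr_losses = []
        for batch in _epoch_batches(len(x_tr), schedule.batch_size, rng):
            logits = net.forward(x_tr[batch], train=True)
            loss, dlogits = nn.weighted_ce_dice_loss(
                logits, y_tr[batch], cmb_weight=cmb_weight
            )
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            tr_losses.append(loss)
        val_loss = _eval_detection_loss(
            net, x_va, y_va, schedule.batch_size, cmb_weight
        )
        rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(tr_losses)),
             "val_loss": float(val_loss), "lr": opt.lr}
        )
        if val_loss < best_val:
            best_val, best_state, best_epoch = val_loss, nn.get_state(net), epoch
        elif epoch - best_epoch >= schedule.patience:
            break
    nn.set_state(net, best_state)
    return DetectorModel(
        net=net, config=config, trained=True, log=pd.DataFrame(rows)
    )


def _pad_to_multiple(x: np.ndarray, mult: int) -> tuple[np.ndarray, tuple]:
    pads = [(0, (-s) % mult) for s in x.shape[:3]]
    xp = np.pad(x, pads + [(0, 0)])
    return xp, tuple(pads)


def predict_candidates(
    pvol: PreprocessedVolume,
    frst: FRSTMap,
    model: DetectorModel,
    mask: BrainMask | None = None,
) -> CandidateMap:
    """Whole-image fully convolutional inference producing P_Cdet in [0, 1]."""
    if not model.trained:
        raise ContractError("detector has not been trained")
    if pvol.shape != frst.shape:
        raise ContractError("image and FRST grids differ")
    x = np.stack([pvol.data, frst.data], axis=-1).astype(np.float32)
    xp, pads = _pad_to_multiple(x, 4)
    logits = model.net.forward(xp[None], train=False)[0]
    probs = nn.softmax(logits.astype(np.float64), axis=-1)[..., 1]
    sl = tuple(slice(0, s) for s in pvol.shape)
    probs = probs[sl]
    if mask is not None:
        probs = probs * mask.data
    return CandidateMap(data=probs.astype(np.float32))


def save_checkpoint(model, path: str | Path, extra: dict | None = None) -> None:
    """Serialize network weights (.npz) with a JSON architecture sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    state = nn.get_state(model.net if hasattr(model, "net") else model)
    np.savez(path, **{f"p{i}": arr for i, arr in enumerate(state)})
    sidecar = {"n_arrays": len(state)}
    if extra:
        sidecar.update(extra)
    if hasattr(model, "config"):
        sidecar["config"] = asdict(model.config)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_detector(path: str | Path) -> DetectorModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = DetectorConfig(**sidecar["config"])
    model = DetectorModel(net=config.build(), config=config, trained=True)
    with np.load(path) as z:
        state = [z[f"p{i}"] for i in range(sidecar["n_arrays"])]
    nn.set_state(model.net, state)
    return model
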