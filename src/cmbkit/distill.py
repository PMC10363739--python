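"""Candidate discrimination with offline response-based knowledge distillation.

A multi-tasking *teacher* shares a convolutional feature extractor (T_f)
between a voxel-wise segmentor arm (T_s, the same architecture as the
candidate detector and optionally initialised from its pretrained weights)
and a patch-level classifier arm (T_c).  A lightweight *student* (feature
extractor + classifier only) is then trained on patches centred at detected
candidates, matching both the hard labels and the teacher classifier's
temperature-softened distribution:

    L = alpha * CE(y_S, sigma(z_S, tau=1)) + beta * KL(sigma(z_S, tau), sigma(z_Tc, tau))

with the student's softened distribution as the first KL argument.  No
tau^2 rescaling is applied to the distillation term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .detector import DetectorModel, TrainSchedule
from .errors import ContractError, ParameterError
from .sampling import Candidate, PatchSet

__all__ = [
    "KDLossParams",
    "TeacherConfig",
    "StudentConfig",
    "TeacherModel",
    "StudentModel",
    "softmax_with_temperature",
    "kd_loss",
    "total_student_loss",
    "train_teacher",
    "train_student",
    "classify_candidates",
]


@dataclass
class KDLossParams:
    """Distillation temperature and loss weights."""

    tau: float = 4.0
    alpha: float = 0.4
    beta: float = 0.6

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ParameterError("temperature must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("loss weights must be >= 0")


@dataclass
class TeacherConfig:
    in_channels: int = 2
    projection_channels: int = 3
    base_width: int = 64
    classifier_width: int = 64
    fc_sizes: tuple[int, int, int] = (1024, 128, 32)
    dropout: float = 0.2
    patch_size: int = 24
    init_sigma: float | None = 0.05
    seed: int = 0

    def build(self, dtype=np.float32) -> nn.TeacherNet:
        rng = np.random.default_rng(self.seed)
        return nn.TeacherNet(
            cin=self.in_channels,
            proj=self.projection_channels,
            base=self.base_width,
            cls_width=self.classifier_width,
            fc_sizes=self.fc_sizes,
            patch_size=self.patch_size,
            dropout=self.dropout,
            rng=rng,
            sigma=self.init_sigma,
            dtype=dtype,
        )


@dataclass
class StudentConfig:
    """Student capacity: the teacher's shape at half the channel counts."""

    in_channels: int = 2
    projection_channels: int = 3
    base_width: int = 32
    classifier_width: int = 32
    fc_sizes: tuple[int, int, int] = (512, 64, 16)
    dropout: float = 0.2
    patch_size: int = 24
    init_sigma: float | None = 0.05
    seed: int = 0

    @classmethod
    def half_of(cls, teacher: TeacherConfig, seed: int | None = None
                ) -> "StudentConfig":
        return cls(
            in_channels=teacher.in_channels,
            projection_channels=teacher.projection_channels,
            base_width=max(1, teacher.base_width // 2),
            classifier_width=max(1, teacher.classifier_width // 2),
            fc_sizes=tuple(max(2, s // 2) for s in teacher.fc_sizes),
            dropout=teacher.dropout,
            patch_size=teacher.patch_size,
            init_sigma=teacher.init_sigma,
            seed=teacher.seed if seed is None else seed,
        )

    def build(self, dtype=np.float32) -> nn.StudentNet:
        rng = np.random.default_rng(self.seed)
        return nn.StudentNet(
            cin=self.in_channels,
            proj=self.projection_channels,
            base=self.base_width,
            cls_width=self.classifier_width,
            fc_sizes=self.fc_sizes,
            patch_size=self.patch_size,
            dropout=self.dropout,
            rng=rng,
            sigma=self.init_sigma,
            dtype=dtype,
        )


@dataclass
class TeacherModel:
    net: nn.TeacherNet
    config: TeacherConfig
    trained: bool = False
    log: pd.DataFrame | None = None


@dataclass
class StudentModel:
    net: nn.StudentNet
    config: StudentConfig
    trained: bool = False
    log: pd.DataFrame | None = None


# public loss surface -------------------------------------------------------


def softmax_with_temperature(z, tau: float) -> np.ndarray:
    """Temperature-softened softmax over the last axis."""
    return nn.softmax_with_temperature(z, tau)


def kd_loss(z_s, z_t, tau: float) -> float:
    """KL(sigma(z_S, tau) || sigma(z_Tc, tau)); 0 iff the softened
    distributions coincide."""
    return nn.kd_loss_value(z_s, z_t, tau)


def total_student_loss(z_s, y_s, z_t, params: KDLossParams) -> float:
    """alpha*CE + beta*KD as used to train the student."""
    return nn.total_student_loss_value(
        z_s, y_s, z_t, params.tau, params.alpha, params.beta
    )


# training ------------------------------------------------------------------


def _check_patch_size(patchset: PatchSet, size: int) -> None:
    for p in patchset:
        if p.size != size:
            raise ContractError(f"expected {size}^3 patches, got {p.size}^3")


def train_teacher(
    train_patches: PatchSet,
    val_patches: PatchSet,
    schedule: TrainSchedule,
    config: TeacherConfig,
    detector: DetectorModel | None = None,
    cmb_weight: float = 10.0,
) -> TeacherModel:
    """Jointly train segmentor and classifier arms with a shared extractor.

    The segmentor arm minimises the detection loss (weighted CE + Dice); the
    classifier arm minimises binary cross-entropy; gradients are summed into
    the shared features.  If a pretrained detector is given, its weights
    initialise T_f + T_s.
    """
    if len(train_patches) == 0 or len(val_patches) == 0:
        raise ContractError("empty teacher patch set")
    _check_patch_size(train_patches, config.patch_size)
    net = config.build()
    if detector is not None:
        net.load_detector_weights(detector.net)
    x_tr = train_patches.stack_images()
    s_tr = train_patches.stack_seg()
    c_tr = train_patches.stack_class()
    x_va = val_patches.stack_images()
    s_va = val_patches.stack_seg()
    c_va = val_patches.stack_class()
    opt = nn.Adam(net.params(), lr=schedule.lr0, eps=schedule.adam_eps)
    rng = np.random.default_rng(schedule.seed)
    best_val, best_state, best_epoch = np.inf, nn.get_state(net), -1
    rows = []
    for epoch in range(schedule.max_epochs):
        opt.lr = schedule.lr_at(epoch)
        seg_losses, cls_losses = [], []
        order = rng.permutation(len(x_tr))
        for i in range(0, len(order), schedule.batch_size):
            b = order[i:i + schedule.batch_size]
            seg_logits, cls_logits = net.forward(x_tr[b], train=True)
            seg_loss, dseg = nn.weighted_ce_dice_loss(
                seg_logits, s_tr[b], cmb_weight=cmb_weight
            )
            cls_loss, dcls = nn.ce_loss(cls_logits, c_tr[b])
            opt.zero_grad()
            net.backward(dseg, dcls)
            opt.step()
            seg_losses.append(seg_loss)
            cls_losses.append(cls_loss)
        # validation
        v_seg, v_cls, cnt = 0.0, 0.0, 0
        for i in range(0, len(x_va), schedule.batch_size):
            seg_logits, cls_logits = net.forward(
                x_va[i:i + schedule.batch_size], train=False
            )
            sl, _ = nn.weighted_ce_dice_loss(
                seg_logits, s_va[i:i + schedule.batch_size], cmb_weight=cmb_weight
            )
            cl, _ = nn.ce_loss(cls_logits, c_va[i:i + schedule.batch_size])
            nb = len(x_va[i:i + schedule.batch_size])
            v_seg += sl * nb
            v_cls += cl * nb
            cnt += nb
        val_loss = (v_seg + v_cls) / max(cnt, 1)
        rows.append(
            {
                "epoch": epoch,
                "train_seg_loss": float(np.mean(seg_losses)),
                "train_cls_loss": float(np.mean(cls_losses)),
                "val_loss": float(val_loss),
                "lr": opt.lr,
            }
        )
        if val_loss < best_val:
            best_val, best_state, best_epoch = val_loss, nn.get_state(net), epoch
        elif epoch - best_epoch >= schedule.patience:
            break
    nn.set_state(net, best_state)
    return TeacherModel(net=net, config=config, trained=True,
                        log=pd.DataFrame(rows))


def train_student(
    train_patches: PatchSet,
    val_patches: PatchSet,
    teacher: TeacherModel,
    params: KDLossParams,
    schedule: TrainSchedule,
    config: StudentConfig | None = None,
) -> StudentModel:
    """Offline response-based distillation on candidate-centred patches.

    The frozen teacher's classifier logits are recomputed on the same
    (possibly augmented) inputs as the student sees; setting beta=0 reduces
    training to a plain classifier with alpha-scaled cross-entropy.
    """
    if len(train_patches) == 0:
        raise ContractError("empty candidate patch set")
    if not teacher.trained:
        raise ContractError("teacher must be trained before distillation")
    config = config or StudentConfig.half_of(teacher.config)
    _check_patch_size(train_patches, config.patch_size)
    net = config.build()
    if nn.n_parameters(net) >= nn.n_parameters(teacher.net):
        raise ContractError("student must be smaller than the teacher")
    x_tr = train_patches.stack_images()
    y_tr = train_patches.stack_class()
    x_va = val_patches.stack_images() if len(val_patches) else None
    y_va = val_patches.stack_class() if len(val_patches) else None

    def teacher_logits(x):
        _, cls_logits = teacher.net.forward(x, train=False)
        return cls_logits

    opt = nn.Adam(net.params(), lr=schedule.lr0, eps=schedule.adam_eps)
    rng = np.random.default_rng(schedule.seed)
    best_val, best_state, best_epoch = np.inf, nn.get_state(net), -1
    rows = []
    for epoch in range(schedule.max_epochs):
        opt.lr = schedule.lr_at(epoch)
        losses = []
        order = rng.permutation(len(x_tr))
        for i in range(0, len(order), schedule.batch_size):
            b = order[i:i + schedule.batch_size]
            z_t = teacher_logits(x_tr[b])
            z_s = net.forward(x_tr[b], train=True)
            loss, dz = nn.total_student_loss_value(
                z_s, y_tr[b], z_t, params.tau, params.alpha, params.beta,
                with_grad=True,
            )
            opt.zero_grad()
            net.backward(dz.astype(z_s.dtype))
            opt.step()
            losses.append(loss)
        if x_va is not None:
            v, cnt = 0.0, 0
            for i in range(0, len(x_va), schedule.batch_size):
                xb = x_va[i:i + schedule.batch_size]
                z_t = teacher_logits(xb)
                z_s = net.forward(xb, train=False)
                v += nn.total_student_loss_value(
                    z_s, y_va[i:i + schedule.batch_size], z_t,
                    params.tau, params.alpha, params.beta,
                ) * len(xb)
                cnt += len(xb)
            val_loss = v / max(cnt, 1)
        else:
            val_loss = float(np.mean(losses))
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_loss": float(val_loss), "lr": opt.lr})
        if val_loss < best_val:
            best_val, best_state, best_epoch = val_loss, nn.get_state(net), epoch
        elif epoch - best_epoch >= schedule.patience:
            break
    nn.set_state(net, best_state)
    return StudentModel(net=net, config=config, trained=True,
                        log=pd.DataFrame(rows))


def classify_candidates(
    student: StudentModel,
    patchset: PatchSet,
    candidates: list[Candidate],
    th: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Keep each candidate's full voxel set iff its CMB probability >= th.

    Returns per-candidate records (centroid in voxels and mm, probability,
    retained flag) and the binary map of retained components.
    """
    if not student.trained:
        raise ContractError("student has not been trained")
    retained = np.zeros(shape, dtype=np.uint8)
    rows = []
    if len(patchset) == 0:
        return pd.DataFrame(
            columns=["candidate", "x", "y", "z", "x_mm", "y_mm", "z_mm",
                     "probability", "retained"]
        ), retained
    x = patchset.stack_images()
    probs = []
    for i in range(0, len(x), 8):
        logits = student.net.forward(x[i:i + 8], train=False)
        probs.append(nn.softmax(logits.astype(np.float64), axis=-1)[:, 1])
    probs = np.concatenate(probs)
    by_index = {c.index: c for c in candidates}
    for patch, prob in zip(patchset, probs):
        cand = by_index[patch.candidate_index]
        keep = bool(prob >= th)
        if keep:
            retained[tuple(cand.coords.T)] = 1
        cx, cy, cz = cand.centroid
        rows.append(
            {
                "candidate": cand.index,
                "x": cx, "y": cy, "z": cz,
                "x_mm": cx * spacing[0],
                "y_mm": cy * spacing[1],
                "z_mm": cz * spacing[2],
                "probability": float(prob),
                "retained": keep,
            }
        )
    return pd.DataFrame(rows), retained
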