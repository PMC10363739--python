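"""End-to-end orchestration of the three detection steps.

``prepare_subject`` runs the deterministic front end (FOV crop, intensity
normalisation/inversion, vessel removal + inpainting, FRST); ``train_pipeline``
trains detector -> teacher -> distilled student on prepared subjects; and
``predict_subject`` applies the full chain — candidate detection, candidate
discrimination, morphological clean-up — returning a
:class:`~cmbkit.postprocess.DetectionResult` on the original grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .detector import (
    CandidateMap,
    DetectorModel,
    predict_candidates,
    train_detector,
)
from .distill import (
    StudentConfig,
    StudentModel,
    TeacherModel,
    classify_candidates,
    train_student,
    train_teacher,
)
from .errors import ContractError
from .frst import FRSTMap, frst_mean
from .imaging import BrainMask, LabelMap, Volume, crop_to_mask
from .metrics import EvalResult, evaluate_dataset, evaluate_subject
from .postprocess import DetectionResult, apply_filters, finalize, label_clusters
from .preprocess import (
    PreprocessedVolume,
    compute_vessel_features,
    inpaint,
    mask_vessels,
    normalize_and_orient_contrast,
)
from .sampling import (
    AugmentationSpec,
    Candidate,
    PatchSet,
    augment,
    extract_candidate_patches,
    extract_detection_patches,
    extract_teacher_patches,
)

__all__ = [
    "PreparedSubject",
    "PipelineModels",
    "SubjectPrediction",
    "prepare_subject",
    "train_pipeline",
    "predict_subject",
    "final_map_at",
    "evaluate_predictions",
]


@dataclass
class PreparedSubject:
    """Deterministic front-end products for one subject (cropped grid)."""

    pvol: PreprocessedVolume
    frst: FRSTMap
    mask: BrainMask
    labels: np.ndarray | None
    offset: tuple[int, int, int]
    original_shape: tuple[int, int, int]
    original_mask: np.ndarray
    spacing: tuple[float, float, float]


@dataclass
class PipelineModels:
    detector: DetectorModel
    teacher: TeacherModel
    student: StudentModel
    candidate_train: PatchSet | None = None
    candidate_val: PatchSet | None = None


@dataclass
class SubjectPrediction:
    """Per-subject inference state, reusable across discrimination thresholds."""

    cand_map: CandidateMap
    candidates: list[Candidate]
    records: pd.DataFrame
    prepared: PreparedSubject


def prepare_subject(
    vol: Volume,
    mask: BrainMask,
    cfg: PipelineConfig,
    labels: LabelMap | None = None,
) -> PreparedSubject:
    """Crop, normalise/invert, remove vessels, inpaint, and compute FRST."""
    vol_c, mask_c, offset = crop_to_mask(vol, mask, margin=cfg.crop_margin)
    labels_c = None
    if labels is not None:
        sl = tuple(
            slice(o, o + s) for o, s in zip(offset, vol_c.shape)
        )
        labels_c = labels.data[sl].astype(np.uint8)
    pvol = normalize_and_orient_contrast(vol_c, mask_c, cfg.modality)
    if cfg.preprocess.vessel_removal:
        feats = compute_vessel_features(
            pvol, mask_c, scales_mm=cfg.preprocess.frangi_scales_mm
        )
        vm = mask_vessels(
            feats,
            mask_c,
            k=cfg.preprocess.kmeans_k,
            seed=cfg.preprocess.kmeans_seed,
            elongation_min=cfg.preprocess.elongation_min,
        )
        if vm.any():
            pvol = inpaint(pvol, vm)
    fr = frst_mean(
        pvol,
        radii=cfg.frst.radii,
        mask=mask_c.data,
        alpha=cfg.frst.alpha,
        grad_frac=cfg.frst.grad_frac,
    )
    return PreparedSubject(
        pvol=pvol,
        frst=fr,
        mask=mask_c,
        labels=labels_c,
        offset=offset,
        original_shape=vol.shape,
        original_mask=mask.data,
        spacing=vol.spacing,
    )


def _aug_spec(cfg: PipelineConfig, expansion: int) -> AugmentationSpec:
    a = cfg.augment
    return AugmentationSpec(
        translation_vox=a.translation_vox,
        noise_variance=a.noise_variance,
        smooth_sigma_vox=a.smooth_sigma_vox,
        expansion=expansion,
    )


def _split(items: list, val_fraction: float) -> tuple[list, list]:
    n_val = max(1, int(round(val_fraction * len(items)))) if len(items) > 1 else 0
    if n_val == 0:
        return items, items  # single subject: validate on the training subject
    return items[:-n_val], items[-n_val:]


def train_pipeline(
    prepared: list[PreparedSubject], cfg: PipelineConfig
) -> PipelineModels:
    """Train the three stages on prepared subjects with ground truth.

    Subjects are split into train/validation by ``cfg.val_fraction`` (the
    last subjects are held out for validation).  The teacher's segmentor arm
    is initialised from the trained detector; the student is distilled from
    the frozen teacher on candidate-centred patches.
    """
    if any(p.labels is None for p in prepared):
        raise ContractError("training requires ground-truth labels")
    tr, va = _split(prepared, cfg.val_fraction)

    def collect(extract, size, expansion, seed_offset):
        sets = {"train": [], "val": []}
        for name, subs in (("train", tr), ("val", va)):
            for i, s in enumerate(subs):
                ps = extract(s.pvol, s.frst, s.labels, size=size)
                if name == "train":
                    ps = augment(
                        ps, _aug_spec(cfg, expansion),
                        seed=cfg.seed + seed_offset + i,
                    )
                sets[name].extend(ps.patches)
        return PatchSet(sets["train"]), PatchSet(sets["val"])

    det_tr, det_va = collect(
        extract_detection_patches, 48, cfg.augment.expansion_detection, 1000
    )
    # Rarely, a high-lr short-schedule run collapses into the all-background
    # attractor (every ReLU path dead).  Detect it on the validation patches
    # and restart from a shifted init/shuffling seed.
    for attempt in range(2):
        sched = replace(
            cfg.schedule_detector, seed=cfg.schedule_detector.seed + 1000 * attempt
        )
        det_cfg = replace(cfg.detector, seed=cfg.detector.seed + 1000 * attempt)
        detector = train_detector(
            det_tr, det_va, sched, det_cfg, cmb_weight=cfg.cmb_weight,
        )
        val_max = 0.0
        for s in va:
            cmap = predict_candidates(s.pvol, s.frst, detector, mask=s.mask)
            val_max = max(val_max, float(cmap.data.max()))
        if val_max >= cfg.th_cdet:
            break

    tea_tr, tea_va = collect(
        extract_teacher_patches, cfg.teacher.patch_size,
        cfg.augment.expansion_discrimination, 2000,
    )
    teacher = train_teacher(
        tea_tr, tea_va, cfg.schedule_teacher, cfg.teacher, detector=detector,
        cmb_weight=cfg.cmb_weight,
    )

    cand_tr, cand_va = [], []
    for name, subs in (("train", tr), ("val", va)):
        for i, s in enumerate(subs):
            cmap = predict_candidates(s.pvol, s.frst, detector, mask=s.mask)
            ps, _ = extract_candidate_patches(
                s.pvol, s.frst, cmap.data, th=cfg.th_cdet,
                size=cfg.teacher.patch_size, labels=s.labels,
            )
            if name == "train":
                ps = augment(
                    ps,
                    _aug_spec(cfg, cfg.augment.expansion_discrimination),
                    seed=cfg.seed + 3000 + i,
                )
                cand_tr.extend(ps.patches)
            else:
                cand_va.extend(ps.patches)
    cand_tr, cand_va = PatchSet(cand_tr), PatchSet(cand_va)
    if len(cand_tr) == 0:
        raise ContractError(
            "no candidates above Th_Cdet on the training subjects"
        )
    student_cfg = cfg.student or StudentConfig.half_of(cfg.teacher)
    student = train_student(
        cand_tr, cand_va, teacher, cfg.kd, cfg.schedule_student, student_cfg
    )
    return PipelineModels(
        detector=detector,
        teacher=teacher,
        student=student,
        candidate_train=cand_tr,
        candidate_val=cand_va,
    )


def predict_subject(
    vol: Volume,
    mask: BrainMask,
    models: PipelineModels,
    cfg: PipelineConfig,
    prepared: PreparedSubject | None = None,
) -> tuple[DetectionResult, SubjectPrediction]:
    """Run candidate detection, discrimination and clean-up for one subject."""
    s = prepared or prepare_subject(vol, mask, cfg)
    cmap = predict_candidates(s.pvol, s.frst, models.detector, mask=s.mask)
    cmap.threshold_used = cfg.th_cdet
    patches, cands = extract_candidate_patches(
        s.pvol, s.frst, cmap.data, th=cfg.th_cdet, size=cfg.teacher.patch_size
    )
    records, _ = classify_candidates(
        models.student, patches, cands, th=cfg.th_cdisc,
        shape=s.pvol.shape, spacing=s.spacing,
    )
    pred = SubjectPrediction(
        cand_map=cmap, candidates=cands, records=records, prepared=s
    )
    result = final_map_at(pred, cfg.th_cdisc, cfg)
    return result, pred


def final_map_at(
    pred: SubjectPrediction, th_cdisc: float, cfg: PipelineConfig
) -> DetectionResult:
    """Post-processed detection result at a given discrimination threshold.

    Candidate probabilities are reused, so FROC sweeps over ``th_cdisc`` do
    not rerun the networks.  Clusters are mapped back to the original grid
    before the skull-distance transform so boundary distances are not
    truncated by the FOV crop.
    """
    s = pred.prepared
    retained_c = np.zeros(s.pvol.shape, dtype=np.uint8)
    prob_c = np.zeros(s.pvol.shape, dtype=np.float32)
    by_index = {c.index: c for c in pred.candidates}
    if len(pred.records):
        for _, row in pred.records.iterrows():
            cand = by_index[int(row["candidate"])]
            prob_c[tuple(cand.coords.T)] = row["probability"]
            if row["probability"] >= th_cdisc:
                retained_c[tuple(cand.coords.T)] = 1
    # map to the original grid, then compute descriptors there
    retained = np.zeros(s.original_shape, dtype=np.uint8)
    prob = np.zeros(s.original_shape, dtype=np.float32)
    sl = tuple(slice(o, o + n) for o, n in zip(s.offset, s.pvol.shape))
    retained[sl] = retained_c
    prob[sl] = prob_c
    clusters = label_clusters(
        retained, s.spacing, brain_mask=s.original_mask, prob_map=prob
    )
    survivors, ledger = apply_filters(clusters, cfg.filters)
    return finalize(
        survivors,
        s.original_shape,
        crop_offset=(0, 0, 0),
        spacing=s.spacing,
        rejection_ledger=ledger,
    )


def evaluate_predictions(
    results: list[DetectionResult], gt: list[LabelMap | np.ndarray]
) -> EvalResult:
    """Cluster-wise evaluation of final maps against ground truth."""
    triples = []
    for r, g in zip(results, gt):
        g_arr = g.data if isinstance(g, LabelMap) else np.asarray(g)
        triples.append(evaluate_subject(r.cmb_map, g_arr.astype(np.uint8)))
    return evaluate_dataset(triples)
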