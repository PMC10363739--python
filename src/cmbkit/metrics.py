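"""Lesion-level evaluation: cluster-wise TPR, FPavg, precision, and FROC.

Clusters are 26-connected components.  A ground-truth cluster counts as
detected (TP) iff at least one of its voxels is covered by any predicted
cluster; a predicted cluster is a false positive iff it overlaps no
ground-truth cluster by at least one voxel.  Multiple predictions hitting one
ground-truth cluster count it once, and none of them count as false
positives.

    cluster-wise TPR       = TP_clus / (TP_clus + FN_clus)
    FPavg                  = total FP_clus / number of subjects
    cluster-wise precision = TP_clus / (TP_clus + FP_clus)

The FROC curve plots TPR against FPavg over a threshold grid; the operating
point is picked at the curve's knee (maximal perpendicular distance from the
chord joining the curve endpoints, in FPavg-normalised coordinates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ContractError

__all__ = ["EvalResult", "evaluate_subject", "evaluate_dataset", "froc",
           "plot_froc"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class EvalResult:
    tp_clus: int
    fn_clus: int
    fp_clus: int
    n_subjects: int

    @property
    def cluster_tpr(self) -> float:
        denom = self.tp_clus + self.fn_clus
        if denom == 0:
            warnings.warn("no ground-truth clusters; TPR undefined")
            return float("nan")
        return self.tp_clus / denom

    @property
    def fp_avg(self) -> float:
        return self.fp_clus / self.n_subjects

    @property
    def cluster_precision(self) -> float:
        denom = self.tp_clus + self.fp_clus
        if denom == 0:
            return float("nan")
        return self.tp_clus / denom


def _check_binary(arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ContractError(f"{what} must be binary")
    return arr.astype(bool)


def evaluate_subject(
    pred_map: np.ndarray, gt_map: np.ndarray
) -> tuple[int, int, int]:
    """Cluster-wise (TP, FN, FP) for one subject under the one-voxel-overlap rule."""
    pred = _check_binary(pred_map, "prediction map")
    gt = _check_binary(gt_map, "ground-truth map")
    if pred.shape != gt.shape:
        raise ContractError("prediction/ground-truth grids differ")
    gt_lab, n_gt = ndimage.label(gt, structure=_STRUCT26)
    pr_lab, n_pr = ndimage.label(pred, structure=_STRUCT26)
    detected_gt = np.unique(gt_lab[pred & (gt_lab > 0)])
    tp = int(len(detected_gt))
    fn = int(n_gt - tp)
    matched_pred = np.unique(pr_lab[gt & (pr_lab > 0)])
    fp = int(n_pr - len(matched_pred))
    return tp, fn, fp


def evaluate_dataset(subject_results: list[tuple[int, int, int]]) -> EvalResult:
    """Aggregate per-subject (TP, FN, FP) counts over a dataset."""
    if len(subject_results) == 0:
        raise ContractError("at least one subject is required")
    tp = sum(r[0] for r in subject_results)
    fn = sum(r[1] for r in subject_results)
    fp = sum(r[2] for r in subject_results)
    return EvalResult(tp_clus=tp, fn_clus=fn, fp_clus=fp,
                      n_subjects=len(subject_results))


def _knee_point(fp_avgs: np.ndarray, tprs: np.ndarray) -> int:
    """Index of the knee: maximal perpendicular distance from the endpoint
    chord, computed with FPavg normalised to [0, 1]; ties go to higher TPR."""
    fmax = fp_avgs.max()
    f = fp_avgs / fmax if fmax > 0 else fp_avgs
    p0 = np.array([f[0], tprs[0]])
    p1 = np.array([f[-1], tprs[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        return int(np.argmax(tprs))
    pts = np.stack([f, tprs], axis=1) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    best = dist.max()
    cand = np.flatnonzero(np.isclose(dist, best))
    return int(cand[np.argmax(tprs[cand])])


def froc(
    prob_maps: list[np.ndarray],
    gt_maps: list[np.ndarray],
    thresholds: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float]:
    """FROC table over a threshold grid plus the knee-point threshold."""
    if thresholds is None:
        thresholds = np.arange(0.05, 0.96, 0.05)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ContractError("empty threshold list")
    if np.any(np.diff(thresholds) < 0):
        raise ContractError("thresholds must be sorted ascending")
    if len(prob_maps) != len(gt_maps) or len(prob_maps) == 0:
        raise ContractError("need matching, nonempty probability/GT map lists")
    rows = []
    for th in thresholds:
        res = evaluate_dataset(
            [
                evaluate_subject((np.asarray(p) >= th).astype(np.uint8), g)
                for p, g in zip(prob_maps, gt_maps)
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(
                {
                    "threshold": float(th),
                    "tpr": res.cluster_tpr,
                    "fp_avg": res.fp_avg,
                    "precision": res.cluster_precision,
                    "tp": res.tp_clus,
                    "fn": res.fn_clus,
                    "fp": res.fp_clus,
                }
            )
    table = pd.DataFrame(rows)
    knee_idx = _knee_point(
        table["fp_avg"].to_numpy(), np.nan_to_num(table["tpr"].to_numpy())
    )
    return table, float(table["threshold"].iloc[knee_idx])


def plot_froc(table: pd.DataFrame, path=None, label: str = "FROC"):
    """Render a FROC curve (TPR vs FPavg) to a file or interactive axes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(table["fp_avg"], table["tpr"], "o-", label=label)
    ax.set_xlabel("average false positives per subject")
    ax.set_ylabel("cluster-wise TPR")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
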