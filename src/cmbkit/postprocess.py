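"""Morphological clean-up of retained candidates.

Three anatomical/shape rules remove the remaining mimics: stray specks with
volume < 2.5 mm^3, tubular fragments with ellipticity > 0.2, and candidates
closer than 5 mm to the brain-mask boundary (sulcal mimics).  Rejections are
attributed to the first triggering rule in the order skull -> volume -> shape
and recorded in a ledger.

Ellipticity is defined from the eigenvalues of the cluster's second-moment
matrix in mm space as ``1 - sqrt(lambda_min / lambda_max)``: ~0 for a sphere,
approaching 1 for a rod.  Each voxel contributes its own box variance
(spacing^2/12) to the moment matrix so single-slice clusters on anisotropic
grids are not degenerate; clusters of fewer than 3 voxels score 0.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ContractError

__all__ = [
    "Cluster",
    "FilterRules",
    "DetectionResult",
    "label_clusters",
    "apply_filters",
    "finalize",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Cluster:
    """One 26-connected component with its physical descriptors."""

    coords: np.ndarray  # (n, 3) voxel indices
    volume_mm3: float
    centroid_mm: tuple[float, float, float]
    ellipticity: float
    distance_to_boundary_mm: float
    probability: float | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.coords)


@dataclass
class FilterRules:
    """Survival thresholds: volume >= 2.5 mm^3, ellipticity <= 0.2,
    skull distance >= 5 mm."""

    min_volume_mm3: float = 2.5
    max_ellipticity: float = 0.2
    min_skull_distance_mm: float = 5.0

    def __post_init__(self) -> None:
        if min(self.min_volume_mm3, self.max_ellipticity,
               self.min_skull_distance_mm) < 0:
            raise ContractError("filter thresholds must be >= 0")


def _ellipticity(coords: np.ndarray, spacing) -> float:
    if len(coords) < 3:
        return 0.0
    xyz = coords * np.asarray(spacing, dtype=float)
    cov = np.cov(xyz.T, ddof=0)
    cov = cov + np.diag(np.asarray(spacing, dtype=float) ** 2 / 12.0)
    lam = np.linalg.eigvalsh(cov)
    lmin, lmax = float(lam[0]), float(lam[-1])
    if lmax <= 0:
        return 0.0
    return float(1.0 - np.sqrt(max(lmin, 0.0) / lmax))


def label_clusters(
    binary_map: np.ndarray,
    spacing: tuple[float, float, float],
    brain_mask: np.ndarray | None = None,
    prob_map: np.ndarray | None = None,
) -> list[Cluster]:
    """26-connected components of a binary map with all descriptors computed.

    Skull distance is the anisotropy-aware Euclidean distance transform of
    the brain mask evaluated at the (rounded) cluster centroid; it is +inf
    when no brain mask is provided.
    """
    binary_map = np.asarray(binary_map)
    vals = np.unique(binary_map)
    if not np.isin(vals, (0, 1)).all():
        raise ContractError("cluster input must be binary")
    voxel_vol = float(np.prod(spacing))
    if brain_mask is not None:
        edt = ndimage.distance_transform_edt(
            np.asarray(brain_mask, dtype=bool), sampling=spacing
        )
    lab, _ = ndimage.label(binary_map.astype(bool), structure=_STRUCT26)
    clusters = []
    for i, sl in enumerate(ndimage.find_objects(lab), start=1):
        coords = np.argwhere(lab[sl] == i) + [s.start for s in sl]
        centroid_vox = coords.mean(axis=0)
        centroid_mm = tuple(float(c * s) for c, s in zip(centroid_vox, spacing))
        if brain_mask is not None:
            cv = tuple(
                int(np.clip(round(c), 0, n - 1))
                for c, n in zip(centroid_vox, binary_map.shape)
            )
            dist = float(edt[cv])
        else:
            dist = float("inf")
        prob = (
            float(np.asarray(prob_map)[tuple(coords.T)].mean())
            if prob_map is not None
            else None
        )
        clusters.append(
            Cluster(
                coords=coords,
                volume_mm3=len(coords) * voxel_vol,
                centroid_mm=centroid_mm,
                ellipticity=_ellipticity(coords, spacing),
                distance_to_boundary_mm=dist,
                probability=prob,
            )
        )
    return clusters


def apply_filters(
    clusters: list[Cluster], rules: FilterRules | None = None
) -> tuple[list[Cluster], list[dict]]:
    """Apply the three survival rules; return survivors and a rejection ledger.

    A cluster survives iff volume >= min_volume AND ellipticity <=
    max_ellipticity AND skull distance >= min_distance.  Dropped clusters are
    attributed to the first rule (skull -> volume -> shape) that rejects
    them, so the ledger partitions the rejected set deterministically.
    """
    rules = rules or FilterRules()
    retained, ledger = [], []
    for idx, c in enumerate(clusters):
        reasons = []
        if c.distance_to_boundary_mm < rules.min_skull_distance_mm:
            reasons.append("skull_distance")
        if c.volume_mm3 < rules.min_volume_mm3:
            reasons.append("volume")
        if c.ellipticity > rules.max_ellipticity:
            reasons.append("shape")
        if reasons:
            ledger.append(
                {
                    "cluster": idx,
                    "rejected_by": reasons[0],
                    "all_failed_rules": reasons,
                    "volume_mm3": c.volume_mm3,
                    "ellipticity": c.ellipticity,
                    "distance_to_boundary_mm": c.distance_to_boundary_mm,
                }
            )
        else:
            retained.append(c)
    return retained, ledger


@dataclass
class DetectionResult:
    """Final binary CMB map on the original grid plus per-CMB records."""

    cmb_map: np.ndarray
    records: pd.DataFrame
    count: int
    rejection_ledger: list[dict] = field(default_factory=list)

    def save_ledger(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.rejection_ledger, indent=2))


def finalize(
    retained: list[Cluster],
    original_shape: tuple[int, int, int],
    crop_offset: tuple[int, int, int] = (0, 0, 0),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    rejection_ledger: list[dict] | None = None,
) -> DetectionResult:
    """Map retained clusters back to the original grid and summarise them."""
    cmb_map = np.zeros(original_shape, dtype=np.uint8)
    off = np.asarray(crop_offset, dtype=int)
    rows = []
    for c in retained:
        coords = c.coords + off
        inb = np.all((coords >= 0) & (coords < np.array(original_shape)), axis=1)
        coords = coords[inb]
        cmb_map[tuple(coords.T)] = 1
        rows.append(
            {
                "x_mm": c.centroid_mm[0] + off[0] * spacing[0],
                "y_mm": c.centroid_mm[1] + off[1] * spacing[1],
                "z_mm": c.centroid_mm[2] + off[2] * spacing[2],
                "volume_mm3": c.volume_mm3,
                "ellipticity": c.ellipticity,
                "distance_to_boundary_mm": c.distance_to_boundary_mm,
                "probability": c.probability,
            }
        )
    records = pd.DataFrame(
        rows,
        columns=["x_mm", "y_mm", "z_mm", "volume_mm3", "ellipticity",
                 "distance_to_boundary_mm", "probability"],
    )
    return DetectionResult(
        cmb_map=cmb_map,
        records=records,
        count=len(retained),
        rejection_ledger=rejection_ledger or [],
    )
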