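"""Intensity normalisation/inversion and vessel/sulcus removal.

The detection networks expect CMBs to be *bright*.  T2*-GRE and SWI volumes
are therefore intensity-normalised (division by the within-mask maximum) and
inverted (subtracted from 1); QSM volumes are only normalised, because
microbleeds are already hyperintense there.

Elongated bright structures (vessels, sulci) are the dominant source of CMB
mimics.  They are found by clustering per-voxel vesselness features — Frangi
filter responses at a few scales plus structure-tensor shape measures
(linearity and planarity) — with K-means, keeping only *linear* segments of
the vessel cluster, and are then removed by inpainting each masked voxel with
the mean of its unmasked 26-neighbours (onion-peeling inward for thick masks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import frangi
from sklearn.cluster import KMeans

from .errors import (
    ContractError,
    DegenerateIntensityError,
    InpaintImpossibleError,
    ParameterError,
)
from .imaging import BrainMask, Volume

__all__ = [
    "PreprocessedVolume",
    "VesselFeatureStack",
    "normalize_and_orient_contrast",
    "compute_vessel_features",
    "mask_vessels",
    "inpaint",
    "component_elongation",
]

MODALITIES = ("T2*GRE", "SWI", "QSM")


@dataclass
class PreprocessedVolume:
    """Brain image mapped to [0, 1] with CMBs bright; background is 0."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str
    vessel_mask: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class VesselFeatureStack:
    """Per-voxel tubularity features: Frangi responses + tensor shape measures."""

    frangi: np.ndarray  # (n_scales, D, H, W)
    linearity: np.ndarray  # (D, H, W)
    planarity: np.ndarray  # (D, H, W)
    scales_mm: tuple[float, ...]


def normalize_and_orient_contrast(
    vol: Volume, mask: BrainMask, modality: str
) -> PreprocessedVolume:
    """Normalise intensities to [0, 1] and make CMBs bright.

    Intensities are divided by the within-mask maximum (never the global
    maximum, to avoid background dominance).  For T2*-GRE/SWI the normalised
    image is subtracted from 1; QSM is left un-inverted.  Voxels outside the
    brain mask are set to 0.
    """
    if modality not in MODALITIES:
        raise ParameterError(f"modality must be one of {MODALITIES}")
    if not mask.matches(vol):
        raise ContractError("mask grid does not match the volume grid")
    m = mask.data
    vals = vol.data[m]
    if vals.size == 0:
        raise ContractError("empty brain mask")
    vmax, vmin = float(vals.max()), float(vals.min())
    if vmax == vmin:
        raise DegenerateIntensityError("image is constant inside the brain mask")
    v = vol.data.astype(np.float64) / vmax
    if modality in ("T2*GRE", "SWI"):
        out = 1.0 - v
    else:
        out = v
    out = np.clip(out, 0.0, 1.0)
    out[~m] = 0.0
    return PreprocessedVolume(
        data=out.astype(np.float32),
        spacing=vol.spacing,
        modality=modality,
        vessel_mask=None,
        provenance=list(vol.provenance)
        + [f"normalised ({'inverted' if modality != 'QSM' else 'not inverted'})"],
    )


def _structure_tensor_shape(
    data: np.ndarray,
    spacing: tuple[float, float, float],
    sigma_grad_vox: float = 1.0,
    sigma_tensor_vox: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Linearity/planarity from the smoothed structure tensor.

    Gradients are taken in mm so anisotropic grids are handled correctly;
    the smoothing sigmas are in voxels.
    """
    sm = ndimage.gaussian_filter(data.astype(np.float64), sigma_grad_vox)
    g = np.gradient(sm, *spacing)
    elems = {}
    for i in range(3):
        for j in range(i, 3):
            elems[(i, j)] = ndimage.gaussian_filter(g[i] * g[j], sigma_tensor_vox)
    tensor = np.empty(data.shape + (3, 3))
    for i in range(3):
        for j in range(3):
            tensor[..., i, j] = elems[(min(i, j), max(i, j))]
    lam = np.linalg.eigvalsh(tensor)[..., ::-1]  # descending: l1 >= l2 >= l3
    l1 = lam[..., 0]
    safe = l1 > 1e-12
    linearity = np.zeros(data.shape)
    planarity = np.zeros(data.shape)
    linearity[safe] = (lam[..., 0] - lam[..., 1])[safe] / l1[safe]
    planarity[safe] = (lam[..., 1] - lam[..., 2])[safe] / l1[safe]
    return linearity, planarity


def compute_vessel_features(
    pvol: PreprocessedVolume,
    mask: BrainMask,
    scales_mm: tuple[float, ...] = (0.5, 1.0, 1.5),
) -> VesselFeatureStack:
    """Frangi vesselness per scale plus structure-tensor linearity/planarity.

    Vessels are bright after inversion, so the Frangi filter is run with
    bright-ridge polarity.  Frangi scales are given in mm and converted to
    voxel sigmas with the mean spacing (the filter itself is isotropic).
    """
    if len(scales_mm) < 1:
        raise ParameterError("at least one Frangi scale is required")
    data = pvol.data.astype(np.float64)
    mean_sp = float(np.mean(pvol.spacing))
    stack = np.stack(
        [
            frangi(data, sigmas=[max(s / mean_sp, 0.25)], black_ridges=False)
            for s in scales_mm
        ]
    )
    stack[:, ~mask.data] = 0.0
    linearity, planarity = _structure_tensor_shape(data, pvol.spacing)
    linearity[~mask.data] = 0.0
    planarity[~mask.data] = 0.0
    if not (
        np.isfinite(stack).all()
        and np.isfinite(linearity).all()
        and np.isfinite(planarity).all()
    ):
        raise ContractError("non-finite vessel features")
    return VesselFeatureStack(
        frangi=stack.astype(np.float32),
        linearity=linearity.astype(np.float32),
        planarity=planarity.astype(np.float32),
        scales_mm=tuple(float(s) for s in scales_mm),
    )


def component_elongation(
    coords: np.ndarray, spacing: tuple[float, float, float]
) -> float:
    """Principal-axis ratio sqrt(lmax/lmin) of a voxel set's mm covariance.

    Each voxel contributes its box variance (spacing^2/12) so that thin
    components on anisotropic grids are measured sensibly.
    """
    xyz = coords * np.asarray(spacing)
    cov = np.cov(xyz.T, ddof=0) if len(xyz) > 1 else np.zeros((3, 3))
    cov = np.atleast_2d(cov)
    if cov.shape != (3, 3):
        cov = np.zeros((3, 3))
    cov = cov + np.diag(np.asarray(spacing, dtype=float) ** 2 / 12.0)
    lam = np.linalg.eigvalsh(cov)
    lmin, lmax = float(lam[0]), float(lam[-1])
    if lmax <= 0:
        return 1.0
    return float(np.sqrt(lmax / max(lmin, 1e-12)))


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def mask_vessels(
    features: VesselFeatureStack,
    mask: BrainMask,
    k: int = 2,
    seed: int = 0,
    elongation_min: float = 3.0,
) -> np.ndarray:
    """K-means over per-voxel features; keep linear segments of the vessel class.

    The cluster with the highest mean vesselness is taken as the vessel
    class.  Only elongated 26-connected components (principal-axis ratio >=
    ``elongation_min`` and >= 3 voxels) are retained as vessels; rounder
    components are returned to the image so that true CMBs near vessels are
    not destroyed.
    """
    if k < 2:
        raise ParameterError("k-means needs at least 2 clusters")
    m = mask.data
    vness = features.frangi.max(axis=0)
    feats = np.column_stack(
        [features.frangi[i][m] for i in range(features.frangi.shape[0])]
        + [features.linearity[m], features.planarity[m]]
    ).astype(np.float64)
    # features share a common [0, 1]-ish scale; clustering on raw values keeps
    # the vesselness magnitudes decisive
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(feats)
    cluster_vness = [
        vness[m][assign == c].mean() if (assign == c).any() else -np.inf
        for c in range(k)
    ]
    vessel_cluster = int(np.argmax(cluster_vness))
    vm = np.zeros(mask.shape, dtype=bool)
    vm[m] = assign == vessel_cluster
    lab, n = ndimage.label(vm, structure=_STRUCT26)
    keep = np.zeros(mask.shape, dtype=bool)
    for obj_idx, sl in enumerate(ndimage.find_objects(lab), start=1):
        coords = np.argwhere(lab[sl] == obj_idx) + [s.start for s in sl]
        if len(coords) < 3:
            continue
        if component_elongation(coords, mask.spacing) >= elongation_min:
            keep[tuple(coords.T)] = True
    return keep


def inpaint(pvol: PreprocessedVolume, vessel_mask: np.ndarray) -> PreprocessedVolume:
    """Replace masked voxels by the mean of their unmasked 26-neighbours.

    Voxels whose 26-neighbourhood is entirely masked are filled iteratively,
    onion-peeling from the mask boundary inward; unmasked voxels are never
    changed.
    """
    vm = np.asarray(vessel_mask, dtype=bool)
    if vm.shape != pvol.shape:
        raise ContractError("vessel mask grid does not match the volume")
    data = pvol.data.astype(np.float64).copy()
    brain = data > 0
    if vm.all() or (brain.any() and (vm | ~brain).all()):
        # nothing but background would remain as an inpainting source
        raise InpaintImpossibleError("removal mask covers the entire brain")
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    remaining = vm.copy()
    while remaining.any():
        known = ~remaining
        ssum = ndimage.correlate(data * known, kernel, mode="constant", cval=0.0)
        cnt = ndimage.correlate(known.astype(np.float64), kernel, mode="constant")
        fill = remaining & (cnt > 0)
        if not fill.any():
            raise InpaintImpossibleError("isolated masked region cannot be filled")
        data[fill] = ssum[fill] / cnt[fill]
        remaining &= ~fill
    return PreprocessedVolume(
        data=data.astype(np.float32),
        spacing=pvol.spacing,
        modality=pvol.modality,
        vessel_mask=vm,
        provenance=list(pvol.provenance)
        + [f"inpainted {int(vm.sum())} vessel/sulcus voxels"],
    )
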