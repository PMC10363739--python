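"""Canonical 3D volume model, NIfTI I/O and coordinate conventions.

All stages of the pipeline share a single convention:

* voxel coordinates are 0-based indices in canonical (RAS) axis order;
* physical quantities (volumes, distances) are always computed in mm using
  the voxel spacing;
* binary maps (brain masks, CMB labels) are strictly {0, 1}.

Volumes are re-ordered to the closest canonical (RAS+) orientation at load
time.  No spatial normalisation (registration) is performed — only the axis
order/polarity is made canonical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DimensionalityError, EmptyMaskError, MetadataError

__all__ = [
    "Volume",
    "BrainMask",
    "LabelMap",
    "read_volume",
    "read_mask",
    "read_labels",
    "write_volume",
    "crop_to_mask",
    "save_crop_offset",
    "load_crop_offset",
]


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    sp = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    return tuple(float(s) for s in sp)


@dataclass
class Volume:
    """A 3D scalar image with spacing (mm/voxel) and orientation metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    orientation_tag: str = "RAS"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got ndim={self.data.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"non-positive voxel spacing: {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        if not np.isfinite(self.data).all():
            raise MetadataError("volume data contains NaN/Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, note: str | None = None) -> "Volume":
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return Volume(
            data=data,
            spacing=self.spacing,
            affine=self.affine.copy(),
            orientation_tag=self.orientation_tag,
            provenance=prov,
        )


def _check_binary(data: np.ndarray, what: str) -> np.ndarray:
    vals = np.unique(data)
    if not np.isin(vals, (0, 1)).all():
        raise MetadataError(f"{what} must be strictly binary, found values {vals[:5]}")
    return data.astype(bool)


@dataclass
class BrainMask:
    """Binary brain mask on the same grid as its companion :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = _check_binary(np.asarray(self.data), "brain mask")
        if self.data.ndim != 3:
            raise DimensionalityError("brain mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def matches(self, vol: Volume) -> bool:
        return self.shape == vol.shape and np.allclose(self.spacing, vol.spacing)


@dataclass
class LabelMap:
    """Binary ground-truth CMB voxel map."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = _check_binary(np.asarray(self.data), "label map")
        if self.data.ndim != 3:
            raise DimensionalityError("label map must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def read_volume(path: str | Path, mask: BrainMask | None = None) -> Volume:
    """Load a NIfTI file as a canonically oriented :class:`Volume`.

    The image is reoriented to the closest RAS+ axis order.  NaN/Inf voxels
    are sanitised to 0 (recorded in provenance); if a brain mask is supplied
    and invalid voxels fall *inside* it, loading fails instead, because a
    corrupt brain voxel cannot be silently repaired.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several I/O error types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if len(img.shape) == 4 and img.shape[3] == 1:
        img = nib.Nifti1Image(
            np.asanyarray(img.dataobj)[..., 0], img.affine, img.header
        )
    elif len(img.shape) != 3:
        raise DimensionalityError(
            f"{path} has shape {img.shape}; expected a 3D volume"
        )
    orig_ornt = "".join(nib.aff2axcodes(img.affine))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    affine = img.affine
    spacing = _spacing_from_affine(affine)
    if any(s <= 0 for s in spacing):
        raise MetadataError(f"{path}: non-positive voxel spacing {spacing}")
    prov = [f"loaded from {path.name} (original orientation {orig_ornt})"]
    bad = ~np.isfinite(data)
    if bad.any():
        if mask is not None and (bad & mask.data).any():
            raise MetadataError(
                f"{path}: {int((bad & mask.data).sum())} NaN/Inf voxels inside "
                "the brain mask"
            )
        data[bad] = 0.0
        prov.append(f"sanitised {int(bad.sum())} NaN/Inf background voxels to 0")
    return Volume(
        data=data,
        spacing=spacing,
        affine=affine,
        orientation_tag="RAS",
        provenance=prov,
    )


def read_mask(path: str | Path) -> BrainMask:
    vol = read_volume(path)
    return BrainMask(
        data=(vol.data > 0.5).astype(np.uint8), spacing=vol.spacing, affine=vol.affine
    )


def read_labels(path: str | Path) -> LabelMap:
    vol = read_volume(path)
    return LabelMap(
        data=(vol.data > 0.5).astype(np.uint8), spacing=vol.spacing, affine=vol.affine
    )


def write_volume(obj: Volume | BrainMask | LabelMap, path: str | Path) -> Path:
    """Write a volume or binary map to NIfTI.

    Binary maps are stored as uint8, scalar volumes (including probability
    maps) as float32, so ``read_volume(write_volume(v))`` round-trips exactly
    at float32 precision.
    """
    path = Path(path)
    if isinstance(obj, (BrainMask, LabelMap)):
        data = obj.data.astype(np.uint8)
    elif isinstance(obj, Volume):
        data = obj.data.astype(np.float32)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    img = nib.Nifti1Image(data, obj.affine)
    img.header.set_zooms(obj.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write NIfTI file {path}: {exc}") from exc
    return path


def crop_to_mask(
    vol: Volume, mask: BrainMask, margin: int = 0
) -> tuple[Volume, BrainMask, tuple[int, int, int]]:
    """Crop image and mask to the mask's bounding box dilated by ``margin``.

    Returns the cropped volume, cropped mask, and the crop offset (the voxel
    index of the cropped origin in the original grid) used to map cluster
    coordinates back to the original grid.
    """
    if not mask.data.any():
        raise EmptyMaskError("cannot crop to an empty brain mask")
    if mask.shape != vol.shape:
        raise MetadataError(
            f"mask shape {mask.shape} does not match volume shape {vol.shape}"
        )
    lo = []
    hi = []
    for axis in range(3):
        proj = mask.data.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.nonzero(proj)[0]
        lo.append(max(int(idx[0]) - margin, 0))
        hi.append(min(int(idx[-1]) + margin + 1, mask.shape[axis]))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    offset = tuple(lo)
    cvol = vol.with_data(vol.data[sl], note=f"cropped to mask bbox, offset {offset}")
    cmask = BrainMask(
        data=mask.data[sl].astype(np.uint8), spacing=mask.spacing, affine=mask.affine
    )
    return cvol, cmask, offset


def save_crop_offset(path: str | Path, offset: tuple[int, int, int]) -> None:
    Path(path).write_text(json.dumps({"crop_offset": list(int(o) for o in offset)}))


def load_crop_offset(path: str | Path) -> tuple[int, int, int]:
    return tuple(json.loads(Path(path).read_text())["crop_offset"])
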