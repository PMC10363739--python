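"""Patch extraction for the three training regimes, and safe augmentation.

Three kinds of patches feed the networks:

* 48-voxel detection patches — non-overlapping tiling, with voxel-wise
  segmentation labels, for the candidate detector;
* 24-voxel teacher patches — non-overlapping tiling, with both segmentation
  labels and a patch class label (CMB iff the patch contains >= 1 ground-truth
  CMB voxel), for the multi-tasking teacher;
* 24-voxel candidate patches — one per 26-connected component of the
  thresholded candidate probability map, centred at the component centroid,
  for the student classifier.

Augmentation deliberately avoids rotation and rescaling (which can destroy
tiny lesions): random in-plane integer translation, Gaussian noise injection
and slight Gaussian smoothing, combined randomly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ContractError
from .frst import FRSTMap
from .preprocess import PreprocessedVolume

__all__ = [
    "Patch",
    "PatchSet",
    "AugmentationSpec",
    "Candidate",
    "candidates_from_map",
    "extract_detection_patches",
    "extract_teacher_patches",
    "extract_candidate_patches",
    "augment",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Patch:
    """A fixed-size 2-channel 3D patch (image + FRST), channels last."""

    image: np.ndarray  # (S, S, S, 2) float32
    seg_label: np.ndarray | None = None  # (S, S, S) uint8
    class_label: int | None = None  # 1 = CMB, 0 = non-CMB
    center: tuple[int, int, int] | None = None
    candidate_index: int | None = None

    @property
    def size(self) -> int:
        return self.image.shape[0]


@dataclass
class PatchSet:
    patches: list[Patch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def __getitem__(self, i) -> Patch:
        return self.patches[i]

    def stack_images(self) -> np.ndarray:
        return np.stack([p.image for p in self.patches]).astype(np.float32)

    def stack_seg(self) -> np.ndarray:
        return np.stack([p.seg_label for p in self.patches]).astype(np.int64)

    def stack_class(self) -> np.ndarray:
        return np.array([p.class_label for p in self.patches], dtype=np.int64)


@dataclass
class AugmentationSpec:
    """Augmentation parameter ranges (defaults follow the training recipe)."""

    translation_vox: tuple[int, int] = (-15, 15)
    noise_variance: tuple[float, float] = (0.01, 0.04)
    smooth_sigma_vox: tuple[float, float] = (0.1, 0.2)
    expansion: int = 10


def _channels(pvol: PreprocessedVolume, frst: FRSTMap) -> np.ndarray:
    if pvol.shape != frst.shape:
        raise ContractError("image and FRST grids differ")
    return np.stack([pvol.data, frst.data], axis=-1).astype(np.float32)


def _tile(channels: np.ndarray, labels: np.ndarray | None, size: int):
    shape = channels.shape[:3]
    n_tiles = [max(1, int(np.ceil(s / size))) for s in shape]
    pad = [(0, n * size - s) for n, s in zip(n_tiles, shape)]
    ch = np.pad(channels, pad + [(0, 0)])
    lab = np.pad(labels, pad) if labels is not None else None
    out = []
    for i in range(n_tiles[0]):
        for j in range(n_tiles[1]):
            for k in range(n_tiles[2]):
                sl = (
                    slice(i * size, (i + 1) * size),
                    slice(j * size, (j + 1) * size),
                    slice(k * size, (k + 1) * size),
                )
                seg = lab[sl].astype(np.uint8) if lab is not None else None
                center = tuple(s.start + size // 2 for s in sl)
                out.append((ch[sl + (slice(None),)], seg, center))
    return out


def extract_detection_patches(
    pvol: PreprocessedVolume,
    frst: FRSTMap,
    labels: np.ndarray,
    size: int = 48,
) -> PatchSet:
    """Non-overlapping tiling into ``size``-voxel patches with seg labels."""
    channels = _channels(pvol, frst)
    labels = np.asarray(labels)
    if labels.shape != pvol.shape:
        raise ContractError("label grid does not match the volume")
    tiles = _tile(channels, labels, size)
    return PatchSet(
        [Patch(image=c, seg_label=s, center=ctr) for c, s, ctr in tiles]
    )


def extract_teacher_patches(
    pvol: PreprocessedVolume,
    frst: FRSTMap,
    labels: np.ndarray,
    size: int = 24,
) -> PatchSet:
    """Adjacent ``size``-voxel tiling with seg labels and patch class labels."""
    ps = extract_detection_patches(pvol, frst, labels, size=size)
    for p in ps:
        p.class_label = int(p.seg_label.any())
    return ps


@dataclass
class Candidate:
    """One 26-connected component of the thresholded candidate map."""

    index: int
    coords: np.ndarray  # (n, 3) voxel indices
    centroid: tuple[float, float, float]
    mean_prob: float


def candidates_from_map(cand_map: np.ndarray, th: float) -> list[Candidate]:
    """Threshold a probability map and return its 26-connected components."""
    binary = np.asarray(cand_map) >= th
    lab, n = ndimage.label(binary, structure=_STRUCT26)
    out = []
    for i, sl in enumerate(ndimage.find_objects(lab), start=1):
        coords = np.argwhere(lab[sl] == i) + [s.start for s in sl]
        centroid = tuple(float(c) for c in coords.mean(axis=0))
        out.append(
            Candidate(
                index=i - 1,
                coords=coords,
                centroid=centroid,
                mean_prob=float(np.asarray(cand_map)[tuple(coords.T)].mean()),
            )
        )
    return out


def _window(channels, labels, center, size):
    """Extract a size^3 window centred at ``center``, zero-padded at borders."""
    shape = channels.shape[:3]
    half = size // 2
    img = np.zeros((size, size, size, channels.shape[-1]), dtype=np.float32)
    seg = np.zeros((size, size, size), dtype=np.uint8) if labels is not None else None
    src, dst = [], []
    for a in range(3):
        lo = center[a] - half
        hi = lo + size
        s_lo, s_hi = max(lo, 0), min(hi, shape[a])
        src.append(slice(s_lo, s_hi))
        dst.append(slice(s_lo - lo, s_hi - lo))
    img[tuple(dst) + (slice(None),)] = channels[tuple(src) + (slice(None),)]
    if seg is not None:
        seg[tuple(dst)] = labels[tuple(src)]
    return img, seg


def extract_candidate_patches(
    pvol: PreprocessedVolume,
    frst: FRSTMap,
    cand_map: np.ndarray,
    th: float,
    size: int = 24,
    labels: np.ndarray | None = None,
) -> tuple[PatchSet, list[Candidate]]:
    """One patch per candidate component, centred at its rounded centroid.

    In training mode (``labels`` given) the class label is CMB iff the
    component overlaps the ground truth by at least one voxel.  An empty
    candidate set is valid and yields an empty PatchSet.
    """
    channels = _channels(pvol, frst)
    if np.asarray(cand_map).shape != pvol.shape:
        raise ContractError("candidate map grid does not match the volume")
    cands = candidates_from_map(cand_map, th)
    gt = np.asarray(labels).astype(bool) if labels is not None else None
    patches = []
    for c in cands:
        center = tuple(int(round(v)) for v in c.centroid)
        img, seg = _window(channels, labels, center, size)
        cls = None
        if gt is not None:
            cls = int(gt[tuple(c.coords.T)].any())
        patches.append(
            Patch(
                image=img,
                seg_label=seg,
                class_label=cls,
                center=center,
                candidate_index=c.index,
            )
        )
    return PatchSet(patches), cands


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _translate(arr: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Integer in-plane translation with zero fill (first two axes)."""
    out = np.zeros_like(arr)
    s = arr.shape
    sx = (slice(max(dx, 0), min(s[0] + dx, s[0])),
          slice(max(-dx, 0), min(s[0] - dx, s[0])))
    sy = (slice(max(dy, 0), min(s[1] + dy, s[1])),
          slice(max(-dy, 0), min(s[1] - dy, s[1])))
    if sx[0].start >= sx[0].stop or sy[0].start >= sy[0].stop:
        return out
    out[sx[0], sy[0]] = arr[sx[1], sy[1]]
    return out


def _augment_once(patch: Patch, spec: AugmentationSpec, rng) -> Patch:
    is_cmb = bool(
        (patch.class_label == 1)
        or (patch.seg_label is not None and patch.seg_label.any())
    )
    for _ in range(25):
        use = rng.random(3) < 0.5
        if not use.any():
            continue
        img = patch.image
        seg = patch.seg_label
        if use[0]:
            dx = int(rng.integers(spec.translation_vox[0], spec.translation_vox[1] + 1))
            dy = int(rng.integers(spec.translation_vox[0], spec.translation_vox[1] + 1))
            img = _translate(img, dx, dy)
            if seg is not None:
                seg = _translate(seg, dx, dy)
            if is_cmb and seg is not None and not seg.any():
                continue  # translation pushed every CMB voxel out; redraw
        if use[1]:
            var = rng.uniform(*spec.noise_variance)
            img = img + rng.normal(0.0, np.sqrt(var), img.shape)
        if use[2]:
            sigma = rng.uniform(*spec.smooth_sigma_vox)
            img = ndimage.gaussian_filter(
                img.astype(np.float64), sigma=(sigma, sigma, sigma, 0.0)
            )
        return Patch(
            image=img.astype(np.float32),
            seg_label=None if seg is None else seg.copy(),
            class_label=patch.class_label,
            center=patch.center,
            candidate_index=patch.candidate_index,
        )
    # fall back to a noise-only copy if every draw emptied the lesion
    var = rng.uniform(*spec.noise_variance)
    img = patch.image + rng.normal(0.0, np.sqrt(var), patch.image.shape)
    return Patch(
        image=img.astype(np.float32),
        seg_label=None if patch.seg_label is None else patch.seg_label.copy(),
        class_label=patch.class_label,
        center=patch.center,
        candidate_index=patch.candidate_index,
    )


def augment(patchset: PatchSet, spec: AugmentationSpec, seed: int) -> PatchSet:
    """Expand a PatchSet by ``spec.expansion``: originals + augmented copies.

    Each augmented patch applies a random non-empty subset of {translation,
    noise injection, Gaussian smoothing}; segmentation labels are translated
    identically (nearest-neighbour, i.e. integer shifts); class labels are
    preserved; CMB patches always retain at least one CMB voxel.
    """
    rng = np.random.default_rng(seed)
    out = [
        Patch(
            image=p.image.copy(),
            seg_label=None if p.seg_label is None else p.seg_label.copy(),
            class_label=p.class_label,
            center=p.center,
            candidate_index=p.candidate_index,
        )
        for p in patchset
    ]
    for p in patchset:
        for _ in range(spec.expansion - 1):
            out.append(_augment_once(p, spec, rng))
    return PatchSet(out)
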