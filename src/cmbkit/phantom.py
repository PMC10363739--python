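"""Seeded synthetic 3D phantoms for training and testing the pipeline.

The phantoms imitate the *statistical* structure the detection method relies
on — not MR physics.  Each subject consists of:

* an ellipsoidal brain mask on an (optionally anisotropic) voxel grid;
* smooth low-frequency tissue intensity variation;
* quasi-spherical CMBs of 2–10 mm diameter with the modality's contrast
  polarity (hypointense on T2*-GRE/SWI, hyperintense on QSM);
* curved tubular vessel mimics with the same polarity as CMBs;
* small boundary-adjacent blob mimics (< 5 mm from the mask edge), which the
  skull-distance rule of the post-processing stage is meant to reject;
* additive Gaussian noise.

Every object is recorded in a truth ledger so tests can check each stage
against known geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import PlacementError
from .imaging import BrainMask, LabelMap, Volume, write_volume

__all__ = ["PhantomSpec", "generate_subject", "generate_subjects", "generate_dataset"]

MODALITIES = ("T2*GRE", "SWI", "QSM")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Sizes are in mm unless stated otherwise.  CMB diameters default to the
    2–10 mm range reported for real microbleeds.  ``min_cmb_depth_mm`` keeps
    CMB centres away from the mask boundary, matching the anatomical
    assumption of the post-processing stage (candidates closer than 5 mm to
    the skull are treated as sulcal mimics).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_cmbs: tuple[int, int] = (3, 8)
    cmb_diameter_mm: tuple[float, float] = (2.0, 10.0)
    cmb_contrast: tuple[float, float] = (0.5, 0.9)
    n_vessels: int = 2
    vessel_radius_mm: tuple[float, float] = (0.5, 1.2)
    vessel_contrast: float = 0.6
    n_boundary_mimics: int = 2
    mimic_diameter_mm: tuple[float, float] = (2.0, 4.0)
    noise_sigma: float = 0.05
    modality: str = "SWI"
    intensity_scale: float = 500.0
    min_cmb_depth_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")


def _coordinate_grids_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _soft_ball(grids_mm, center_mm, radius_mm, edge_mm=0.4):
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids_mm, center_mm)))
    return 1.0 / (1.0 + np.exp((d - radius_mm) / edge_mm)), d


def _place_center(rng, valid, n_tries=200):
    idx = np.argwhere(valid)
    if idx.size == 0:
        return None
    return tuple(idx[rng.integers(len(idx))])


def generate_subject(
    spec: PhantomSpec,
) -> tuple[Volume, BrainMask, LabelMap, list[dict]]:
    """Generate one phantom subject: (volume, brain mask, CMB labels, ledger)."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    grids = _coordinate_grids_mm(shape, spacing)
    extent = [n * s for n, s in zip(shape, spacing)]
    center = [e / 2 for e in extent]

    # ellipsoidal brain mask (sized well inside the FOV)
    semi = (0.345 * extent[0], 0.315 * extent[1], 0.315 * extent[2])
    mask = (
        sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)) <= 1.0
    )

    # smooth tissue background in [~0.45, ~0.65]
    lowfreq = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=6.0)
    amp = np.abs(lowfreq).max()
    tissue = 0.55 + 0.08 * (lowfreq / amp if amp > 0 else lowfreq)

    dark = spec.modality in ("T2*GRE", "SWI")  # CMBs hypointense pre-inversion

    def stamp(profile, contrast):
        nonlocal tissue
        if dark:
            tissue = tissue * (1.0 - contrast * profile)
        else:
            tissue = tissue + contrast * profile

    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    ledger: list[dict] = []

    # vessels: random-walk centrelines marked on the grid, dilated to tubes
    vessel_vox = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_vessels):
        r_mm = rng.uniform(*spec.vessel_radius_mm)
        start = _place_center(rng, edt > 4.0)
        if start is None:
            continue
        pos = np.array(start, dtype=float)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        line = np.zeros(shape, dtype=bool)
        n_steps = int(0.6 * max(shape))
        for _ in range(n_steps):
            ijk = tuple(np.clip(np.round(pos).astype(int), 0, np.array(shape) - 1))
            if not mask[ijk]:
                break
            line[ijk] = True
            direction += 0.25 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pos += direction * (1.0 / np.array(spacing))  # ~1 mm steps
        if not line.any():
            continue
        dist = ndimage.distance_transform_edt(~line, sampling=spacing)
        tube = (dist <= r_mm) & mask
        profile = np.clip(1.0 - dist / max(r_mm, 1e-6), 0.0, 1.0) * mask
        stamp(profile, spec.vessel_contrast)
        vessel_vox |= tube
        ledger.append(
            {
                "type": "vessel",
                "radius_mm": float(r_mm),
                "n_voxels": int(tube.sum()),
            }
        )

    vessel_dist = (
        ndimage.distance_transform_edt(~vessel_vox, sampling=spacing)
        if vessel_vox.any()
        else np.full(shape, np.inf)
    )

    # CMBs: quasi-spherical, deep, mutually separated (largest placed first)
    labels = np.zeros(shape, dtype=np.uint8)
    n_cmbs = int(rng.integers(spec.n_cmbs[0], spec.n_cmbs[1] + 1))
    placed: list[tuple[np.ndarray, float]] = []
    diameters = sorted(
        rng.uniform(*spec.cmb_diameter_mm, size=n_cmbs), reverse=True
    )
    for d_mm in diameters:
        r_mm = d_mm / 2.0
        ok = False
        for _ in range(400):
            valid = edt >= (r_mm + spec.min_cmb_depth_mm)
            if np.isfinite(vessel_dist).any():
                valid &= vessel_dist >= (r_mm + 3.0)
            c = _place_center(rng, valid)
            if c is None:
                break
            c_mm = np.array([ci * s for ci, s in zip(c, spacing)])
            if all(
                np.linalg.norm(c_mm - p_mm)
                >= max(d_mm, 2 * pr, r_mm + pr + 2.0)
                for p_mm, pr in placed
            ):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place CMB of diameter {d_mm:.1f} mm after retries"
            )
        contrast = rng.uniform(*spec.cmb_contrast)
        profile, dist = _soft_ball(grids, c_mm, r_mm)
        stamp(profile * mask, contrast)
        ball = (dist <= r_mm) & mask
        labels[ball] = 1
        placed.append((c_mm, r_mm))
        ledger.append(
            {
                "type": "cmb",
                "center_voxel": [int(v) for v in c],
                "center_mm": [float(v) for v in c_mm],
                "diameter_mm": float(d_mm),
                "contrast": float(contrast),
                "n_voxels": int(ball.sum()),
            }
        )

    # boundary-adjacent blob mimics (< 5 mm from the mask edge)
    for _ in range(spec.n_boundary_mimics):
        d_mm = rng.uniform(*spec.mimic_diameter_mm)
        c = _place_center(rng, (edt > 1.0) & (edt < 4.0))
        if c is None:
            continue
        c_mm = np.array([ci * s for ci, s in zip(c, spacing)])
        profile, _ = _soft_ball(grids, c_mm, d_mm / 2.0)
        stamp(profile * mask, 0.7)
        ledger.append(
            {
                "type": "boundary_mimic",
                "center_voxel": [int(v) for v in c],
                "diameter_mm": float(d_mm),
            }
        )

    tissue = tissue + rng.normal(0.0, spec.noise_sigma, shape)
    tissue = np.clip(tissue, 0.0, None)
    data = (tissue * spec.intensity_scale * mask).astype(np.float32)

    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    vol = Volume(
        data=data,
        spacing=spacing,
        affine=affine,
        provenance=[f"phantom subject (seed={spec.seed}, modality={spec.modality})"],
    )
    bmask = BrainMask(data=mask.astype(np.uint8), spacing=spacing, affine=affine)
    lmap = LabelMap(data=labels, spacing=spacing, affine=affine)
    return vol, bmask, lmap, ledger


def generate_subjects(
    spec: PhantomSpec, n_subjects: int, seed: int
) -> list[tuple[Volume, BrainMask, LabelMap, list[dict]]]:
    """Generate ``n_subjects`` independent phantoms with derived per-subject seeds."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_subjects)
    return [
        generate_subject(replace(spec, seed=int(s % (2**31 - 1))))
        for s in child_seeds
    ]


def generate_dataset(
    spec: PhantomSpec, n_subjects: int, seed: int, outdir: str | Path
) -> dict:
    """Write ``n_subjects`` phantom triples (image/mask/labels) plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "n_subjects": int(n_subjects), "subjects": []}
    for i, (vol, mask, labels, ledger) in enumerate(
        generate_subjects(spec, n_subjects, seed)
    ):
        stem = f"sub-{i:03d}"
        write_volume(vol, outdir / f"{stem}_img.nii.gz")
        write_volume(mask, outdir / f"{stem}_mask.nii.gz")
        write_volume(labels, outdir / f"{stem}_labels.nii.gz")
        counts: dict[str, int] = {}
        for obj in ledger:
            counts[obj["type"]] = counts.get(obj["type"], 0) + 1
        manifest["subjects"].append(
            {
                "id": stem,
                "image": f"{stem}_img.nii.gz",
                "mask": f"{stem}_mask.nii.gz",
                "labels": f"{stem}_labels.nii.gz",
                "objects": ledger,
                "object_counts": counts,
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
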