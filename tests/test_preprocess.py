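"""Normalisation/inversion, vesselness features, K-means masking, inpainting."""

import numpy as np
import pytest

from cmbkit.errors import (
    DegenerateIntensityError,
    InpaintImpossibleError,
    ParameterError,
)
from cmbkit.imaging import BrainMask, Volume
from cmbkit.preprocess import (
    PreprocessedVolume,
    compute_vessel_features,
    inpaint,
    mask_vessels,
    normalize_and_orient_contrast,
)
from tests.conftest import make_ball, make_tube


def _vol_and_mask(data, spacing=(1.0, 1.0, 1.0)):
    vol = Volume(data=np.asarray(data, dtype=np.float32), spacing=spacing)
    mask = BrainMask(data=np.ones(vol.shape, np.uint8), spacing=spacing)
    return vol, mask


class TestNormalize:
    def test_swi_inverted(self):
        data = np.full((8, 8, 8), 500.0)
        data[4, 4, 4] = 50.0  # dark CMB
        vol, mask = _vol_and_mask(data)
        p = normalize_and_orient_contrast(vol, mask, "SWI")
        assert p.data[4, 4, 4] == pytest.approx(0.9)  # 1 - 50/500

    def test_qsm_not_inverted(self):
        data = np.full((8, 8, 8), 0.1)
        data[4, 4, 4] = 0.15
        data[0, 0, 0] = 0.2  # in-mask max
        vol, mask = _vol_and_mask(data)
        p = normalize_and_orient_contrast(vol, mask, "QSM")
        assert p.data[4, 4, 4] == pytest.approx(0.75)

    def test_constant_image_rejected(self):
        vol, mask = _vol_and_mask(np.full((8, 8, 8), 3.0))
        with pytest.raises(DegenerateIntensityError):
            normalize_and_orient_contrast(vol, mask, "SWI")

    def test_range_and_background(self, swi_phantom):
        vol, mask, _, _ = swi_phantom
        p = normalize_and_orient_contrast(vol, mask, "SWI")
        inside = p.data[mask.data]
        assert inside.min() >= 0.0 and inside.max() <= 1.0
        assert (p.data[~mask.data] == 0).all()

    def test_unknown_modality(self):
        vol, mask = _vol_and_mask(np.random.default_rng(0).random((6, 6, 6)))
        with pytest.raises(ParameterError):
            normalize_and_orient_contrast(vol, mask, "FLAIR")


def _pvol(data, spacing=(1.0, 1.0, 1.0)):
    return PreprocessedVolume(
        data=np.asarray(data, np.float32), spacing=spacing, modality="SWI"
    )


class TestVesselFeatures:
    def test_tube_enhanced_over_background_and_ball(self):
        shape = (24, 24, 24)
        tube = make_tube(shape, axis=0, through=(12, 6, 6), radius=1.0)
        ball = make_ball(shape, (12, 16, 16), 3.0)
        img = 0.2 + 0.6 * np.maximum(tube, ball)
        mask = BrainMask(np.ones(shape, np.uint8), (1, 1, 1))
        feats = compute_vessel_features(_pvol(img), mask)
        vness = feats.frangi.max(axis=0)
        on_axis = vness[4:20, 6, 6].mean()
        background = vness[(tube == 0) & (ball == 0)].mean()
        at_ball_center = vness[12, 16, 16]
        assert on_axis > 5 * background
        assert at_ball_center < on_axis  # Frangi suppresses blobs

    def test_uniform_image_all_zero(self):
        mask = BrainMask(np.ones((12, 12, 12), np.uint8), (1, 1, 1))
        feats = compute_vessel_features(_pvol(np.full((12, 12, 12), 0.5)), mask)
        assert np.allclose(feats.frangi, 0)
        assert np.allclose(feats.linearity, 0)
        assert np.allclose(feats.planarity, 0)

    def test_requires_a_scale(self):
        mask = BrainMask(np.ones((8, 8, 8), np.uint8), (1, 1, 1))
        with pytest.raises(ParameterError):
            compute_vessel_features(_pvol(np.zeros((8, 8, 8))), mask,
                                    scales_mm=())


class TestMaskVessels:
    def test_tube_recalled_ball_excluded(self):
        shape = (28, 28, 28)
        tube = make_tube(shape, axis=0, through=(14, 8, 8), radius=1.0)
        ball = make_ball(shape, (14, 19, 19), 3.0)
        rng = np.random.default_rng(0)
        img = 0.2 + 0.6 * np.maximum(tube, ball) + rng.normal(0, 0.01, shape)
        mask = BrainMask(np.ones(shape, np.uint8), (1, 1, 1))
        feats = compute_vessel_features(_pvol(img), mask)
        vm = mask_vessels(feats, mask, k=2, seed=0)
        tube_recall = (vm & tube.astype(bool)).sum() / tube.sum()
        ball_in = (vm & ball.astype(bool)).sum() / ball.sum()
        assert tube_recall >= 0.8
        assert ball_in <= 0.1

    def test_pure_noise_masks_little(self):
        fractions = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            shape = (24, 24, 24)
            img = 0.5 + rng.normal(0, 0.05, shape)
            mask = BrainMask(np.ones(shape, np.uint8), (1, 1, 1))
            feats = compute_vessel_features(_pvol(img), mask)
            vm = mask_vessels(feats, mask, k=2, seed=seed)
            fractions.append(vm.sum() / mask.data.sum())
        assert np.median(fractions) < 0.05

    def test_k_below_two_rejected(self):
        mask = BrainMask(np.ones((8, 8, 8), np.uint8), (1, 1, 1))
        feats = compute_vessel_features(
            _pvol(np.random.default_rng(1).random((8, 8, 8))), mask
        )
        with pytest.raises(ParameterError):
            mask_vessels(feats, mask, k=1)

    def test_phantom_cmbs_survive_vessel_removal(self, swi_phantom):
        """At most 10% of true CMB voxels fall into the vessel mask."""
        from cmbkit.preprocess import normalize_and_orient_contrast

        vol, mask, labels, _ = swi_phantom
        p = normalize_and_orient_contrast(vol, mask, "SWI")
        feats = compute_vessel_features(p, mask)
        vm = mask_vessels(feats, mask, k=2, seed=0)
        frac = (vm & labels.data.astype(bool)).sum() / max(labels.data.sum(), 1)
        assert frac <= 0.10


class TestInpaint:
    def test_single_voxel_neighbour_mean(self):
        data = np.full((5, 5, 5), 0.4, np.float32)
        vm = np.zeros((5, 5, 5), bool)
        vm[2, 2, 2] = True
        out = inpaint(_pvol(data), vm)
        assert out.data[2, 2, 2] == pytest.approx(0.4)

    def test_partially_masked_neighbourhood(self):
        data = np.full((5, 5, 5), 0.2, np.float32)
        vm = np.zeros((5, 5, 5), bool)
        vm[2, 2, 2] = True
        # mask 13 of the 26 neighbours too; remaining unmasked ones are 0.2
        neigh = [(1, 1, 1), (1, 1, 2), (1, 1, 3), (1, 2, 1), (1, 2, 2),
                 (1, 2, 3), (1, 3, 1), (1, 3, 2), (1, 3, 3), (2, 1, 1),
                 (2, 1, 2), (2, 1, 3), (2, 2, 1)]
        for ijk in neigh:
            vm[ijk] = True
        out = inpaint(_pvol(data), vm)
        assert out.data[2, 2, 2] == pytest.approx(0.2)

    def test_thick_block_filled_to_constant(self):
        data = np.full((9, 9, 9), 0.5, np.float32)
        vm = np.zeros((9, 9, 9), bool)
        vm[3:6, 3:6, 3:6] = True
        out = inpaint(_pvol(data), vm)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-6)

    def test_unmasked_voxels_unchanged(self):
        rng = np.random.default_rng(7)
        data = rng.random((8, 8, 8)).astype(np.float32) + 0.1
        vm = np.zeros((8, 8, 8), bool)
        vm[4, 4, 4] = vm[4, 5, 4] = True
        out = inpaint(_pvol(data), vm)
        np.testing.assert_array_equal(out.data[~vm], data[~vm])

    def test_idempotent_on_constant(self):
        data = np.full((7, 7, 7), 0.3, np.float32)
        vm = np.zeros((7, 7, 7), bool)
        vm[3, 3, 3] = True
        once = inpaint(_pvol(data), vm)
        twice = inpaint(once, vm)
        np.testing.assert_allclose(once.data, twice.data)

    def test_whole_brain_mask_impossible(self):
        data = np.full((6, 6, 6), 0.5, np.float32)
        with pytest.raises(InpaintImpossibleError):
            inpaint(_pvol(data), np.ones((6, 6, 6), bool))
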