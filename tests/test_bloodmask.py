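"""Gradient evidence, white-matter grouping, and the artifact heuristics."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from bloodless.bloodmask import (WMGrouping, expand_blood_mask,
                                 gradient_difference_map, gradient_magnitude,
                                 group_white_matter, recover_main_group_blood,
                                 refine_brain_mask, seed_blood_voxels,
                                 trim_brain_mask_periphery)
from bloodless.config import FWHM_TO_SIGMA, PipelineConfig
from bloodless.types import (BinaryMask, ProbabilityMap, TissueLabels, Volume)


def vol(data, affine=None):
    return Volume(np.asarray(data, dtype=float),
                  np.eye(4) if affine is None else affine)


class TestGradientMagnitude:
    def test_constant_volume_zero(self):
        out = gradient_magnitude(vol(np.full((10, 10, 10), 7.0)), 1.0)
        assert np.max(np.abs(out.data)) <= 1e-12

    def test_linear_ramp_slope(self):
        k = 2.5
        data = k * np.arange(24, dtype=float)[:, None, None] * np.ones((1, 24, 24))
        out = gradient_magnitude(vol(data), 1.0)
        interior = out.data[6:-6, 6:-6, 6:-6]
        assert np.max(np.abs(interior - k) / k) <= 0.01

    def test_matches_convolution_oracle(self, rng):
        data = rng.random((16, 16, 16))
        fwhm = 1.0
        out = gradient_magnitude(vol(data), fwhm)
        # independent oracle: build the truncated Gaussian kernel used by
        # scipy (truncate=4), convolve separably with reflect padding,
        # then central differences
        sigma = fwhm * FWHM_TO_SIGMA
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        sm = data.copy()
        for ax in range(3):
            sm = np.moveaxis(sm, ax, 0)
            padded = np.pad(sm, ((radius, radius), (0, 0), (0, 0)), mode="symmetric")
            conv = np.zeros_like(sm)
            for i, w in enumerate(kernel):
                conv += w * padded[i:i + sm.shape[0]]
            sm = np.moveaxis(conv, 0, ax)
        grads = np.gradient(sm, 1.0, 1.0, 1.0)
        want = np.sqrt(sum(g**2 for g in grads))
        denom = np.maximum(want, 1e-9)
        assert np.max(np.abs(out.data - want) / denom) <= 1e-6


class TestGradientDifference:
    def test_identical_inputs_zero(self, rng):
        g = vol(rng.random((12, 12, 12)))
        out = gradient_difference_map(g, vol(g.data.copy()), 2.0)
        assert np.max(np.abs(out.data)) <= 1e-12

    def test_zero_template_gives_blurred_subject(self, rng):
        g = vol(rng.random((12, 12, 12)))
        out = gradient_difference_map(g, vol(np.zeros((12, 12, 12))), 2.0)
        want = ndimage.gaussian_filter(g.data, 2.0 * FWHM_TO_SIGMA)
        assert np.allclose(out.data, want, atol=1e-12)

    def test_highlights_vessels_on_phantom(self, subject64, template64):
        from bloodless.registration import resample

        subj_grad = gradient_magnitude(subject64.t1_bloody, 1.0)
        tpl_grad = gradient_magnitude(template64.t1, 1.0)
        tpl_in_subj = resample(tpl_grad, subject64.truth_transform(),
                               subject64.t1_bloody, "linear")
        gd = gradient_difference_map(subj_grad, tpl_in_subj, 2.0)
        tube = subject64.truth_blood_mask.astype_bool()
        wm_interior = ndimage.binary_erosion(
            subject64.truth_labels.data == 3, iterations=2
        )
        assert gd.data[tube].mean() > gd.data[wm_interior].mean()


class TestWMGrouping:
    def test_single_blob(self):
        lab = np.zeros((8, 8, 8), dtype=np.uint8)
        lab[2:5, 2:5, 2:5] = 3
        g = group_white_matter(TissueLabels(lab, np.eye(4)), 26)
        assert g.counts[g.main_group_id] == 27
        assert not g.off_main_wm().any()

    def test_two_blobs_largest_wins(self):
        lab = np.zeros((12, 12, 12), dtype=np.uint8)
        lab[1:6, 1:6, 1:6] = 3  # 125 voxels
        lab[9:11, 9:11, 9:11] = 3  # 8 voxels
        g = group_white_matter(TissueLabels(lab, np.eye(4)), 26)
        # flood-fill oracle
        grid, n = ndimage.label(lab == 3, structure=np.ones((3, 3, 3), bool))
        sizes = np.bincount(grid.ravel())
        sizes[0] = 0
        assert g.counts[g.main_group_id] == sizes.max() == 125
        assert g.off_main_wm().sum() == 8

    def test_tie_break_smallest_linear_index(self):
        lab = np.zeros((10, 10, 10), dtype=np.uint8)
        lab[0:2, 0:2, 0:2] = 3
        lab[7:9, 7:9, 7:9] = 3
        g = group_white_matter(TissueLabels(lab, np.eye(4)), 26)
        assert g.main_mask()[0, 0, 0]

    def test_no_wm_rejected(self):
        with pytest.raises(ValueError, match="white-matter"):
            group_white_matter(
                TissueLabels(np.zeros((4, 4, 4), dtype=np.uint8), np.eye(4)), 26
            )

    def test_connectivity_6_separates_diagonal(self):
        lab = np.zeros((4, 4, 4), dtype=np.uint8)
        lab[0, 0, 0] = 3
        lab[1, 1, 1] = 3  # diagonal neighbour
        g26 = group_white_matter(TissueLabels(lab, np.eye(4)), 26)
        g6 = group_white_matter(TissueLabels(lab, np.eye(4)), 6)
        assert (g26.counts > 0).sum() == 1
        assert (g6.counts > 0).sum() == 2


def _toy_scene():
    """Small synthetic scene: main WM slab + detached bright strand."""
    shape = (16, 16, 16)
    lab = np.zeros(shape, dtype=np.uint8)
    lab[2:14, 2:14, 2:8] = 3  # main WM slab
    lab[2:14, 2:14, 8:12] = 2  # GM above
    strand = np.zeros(shape, dtype=bool)
    strand[5:11, 8, 10] = True  # off-main WM-labelled strand in the GM
    lab[strand] = 3
    grouping = group_white_matter(TissueLabels(lab, np.eye(4)), 26)
    gd = np.zeros(shape)
    gd[strand] = 10.0
    gd[lab > 0] += 0.1
    bpm = np.zeros(shape)
    bpm[strand] = 0.8
    # neighbour of the strand also has some probability support
    bpm[5:11, 8, 11] = 0.3
    gd[5:11, 8, 11] = 5.0
    labels = TissueLabels(lab, np.eye(4))
    return labels, grouping, vol(gd), ProbabilityMap(bpm, np.eye(4)), strand


class TestSeeds:
    def test_zero_bpm_gives_empty_seed(self):
        labels, grouping, gd, _, _ = _toy_scene()
        bpm = ProbabilityMap(np.zeros((16, 16, 16)), np.eye(4))
        seed = seed_blood_voxels(labels, grouping, gd, bpm, PipelineConfig())
        assert seed.count() == 0

    def test_bright_offmain_strand_seeded(self):
        labels, grouping, gd, bpm, strand = _toy_scene()
        seed = seed_blood_voxels(labels, grouping, gd, bpm, PipelineConfig())
        assert (seed.astype_bool() & strand).sum() >= 0.8 * strand.sum()

    def test_main_group_never_seeded(self):
        labels, grouping, gd, bpm, _ = _toy_scene()
        # even with overwhelming evidence on main-group voxels
        bpm2 = bpm.data.copy()
        bpm2[grouping.main_mask()] = 1.0
        gd2 = gd.data.copy()
        gd2[grouping.main_mask()] = 100.0
        seed = seed_blood_voxels(labels, grouping, vol(gd2),
                                 ProbabilityMap(bpm2, np.eye(4)), PipelineConfig())
        assert not (seed.astype_bool() & grouping.main_mask()).any()


class TestExpansion:
    def test_empty_seed_empty_output(self):
        labels, grouping, gd, bpm, _ = _toy_scene()
        empty = BinaryMask(np.zeros((16, 16, 16), np.uint8), np.eye(4))
        out = expand_blood_mask(empty, labels, grouping, gd, bpm, PipelineConfig())
        assert out.count() == 0

    def test_fixed_point_when_nothing_eligible(self):
        labels, grouping, gd, bpm, strand = _toy_scene()
        seed = seed_blood_voxels(labels, grouping, gd, bpm, PipelineConfig())
        # forbid all expansion by zeroing probability off-seed
        bpm2 = np.where(seed.astype_bool(), bpm.data, 0.0)
        out = expand_blood_mask(seed, labels, grouping, gd,
                                ProbabilityMap(bpm2, np.eye(4)), PipelineConfig())
        assert np.array_equal(out.data, seed.data)

    def test_superset_of_seed_and_untouched_main(self):
        labels, grouping, gd, bpm, strand = _toy_scene()
        seed = seed_blood_voxels(labels, grouping, gd, bpm, PipelineConfig())
        out = expand_blood_mask(seed, labels, grouping, gd, bpm, PipelineConfig())
        assert not (seed.astype_bool() & ~out.astype_bool()).any()
        assert not (out.astype_bool() & grouping.main_mask()).any()


class TestRecovery:
    def test_low_bpm_changes_nothing(self):
        labels, grouping, gd, bpm, _ = _toy_scene()
        current = BinaryMask(np.zeros((16, 16, 16), np.uint8), np.eye(4))
        low = ProbabilityMap(np.full((16, 16, 16), 0.05), np.eye(4))
        out = recover_main_group_blood(grouping, low, gd, current, PipelineConfig())
        assert np.array_equal(out.data, current.data)

    def test_superset_contract(self, rng):
        labels, grouping, gd, bpm, strand = _toy_scene()
        current = BinaryMask(strand.astype(np.uint8), np.eye(4))
        out = recover_main_group_blood(grouping, bpm, gd, current, PipelineConfig())
        assert not (current.astype_bool() & ~out.astype_bool()).any()

    def test_brightness_gate_blocks_ordinary_wm(self):
        labels, grouping, gd, bpm, _ = _toy_scene()
        current = BinaryMask(np.zeros((16, 16, 16), np.uint8), np.eye(4))
        # overwhelming bpm+gradient evidence on the main group, but the
        # volume is flat: nothing is bright, so nothing may be recovered
        strong = ProbabilityMap(np.full((16, 16, 16), 0.9), np.eye(4))
        gd2 = vol(np.full((16, 16, 16), 50.0))
        t1 = vol(np.full((16, 16, 16), 100.0) + np.arange(16)[:, None, None] * 0.01)
        out = recover_main_group_blood(grouping, strong, gd2, current,
                                       PipelineConfig(), t1_corrected=t1)
        assert out.count() == 0


class TestMaskRefinement:
    def test_empty_blood_keeps_brain(self, rng):
        brain = BinaryMask(rng.integers(0, 2, (6, 6, 6)).astype(np.uint8), np.eye(4))
        if brain.count() == 0:
            brain = BinaryMask(np.ones((6, 6, 6), np.uint8), np.eye(4))
        blood = BinaryMask(np.zeros((6, 6, 6), np.uint8), np.eye(4))
        out = refine_brain_mask(brain, blood)
        assert np.array_equal(out.data, brain.data)

    def test_blood_covering_brain_rejected(self):
        m = BinaryMask(np.ones((4, 4, 4), np.uint8), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            refine_brain_mask(m, m)

    def test_matches_boolean_oracle(self, rng):
        brain = BinaryMask(np.ones((6, 6, 6), np.uint8), np.eye(4))
        blood = BinaryMask(rng.integers(0, 2, (6, 6, 6)).astype(np.uint8), np.eye(4))
        if blood.count() == 216:
            blood.data[0, 0, 0] = 0
        out = refine_brain_mask(brain, blood)
        want = brain.astype_bool() & ~blood.astype_bool()
        assert np.array_equal(out.astype_bool(), want)


class TestTrim:
    def test_interior_blood_leaves_mask_unchanged(self):
        brain = np.zeros((16, 16, 16), dtype=np.uint8)
        brain[2:14, 2:14, 2:14] = 1
        blood = np.zeros_like(brain)
        blood[7:9, 7:9, 7:9] = 1  # strictly interior
        out = trim_brain_mask_periphery(
            BinaryMask(brain, np.eye(4)), BinaryMask(blood, np.eye(4))
        )
        assert np.array_equal(out.data, brain)

    def test_protruding_component_removed(self, subject64, fast_cfg):
        # phantom surface vessels protrude through the brain envelope; after
        # trimming, the voxels outside the (closed) truth envelope are gone
        brain = subject64.brain_mask.astype_bool()
        tube = subject64.truth_blood_mask.astype_bool()
        contaminated = BinaryMask(
            (brain | tube).astype(np.uint8), subject64.brain_mask.affine
        )
        blood = subject64.truth_blood_mask
        out = trim_brain_mask_periphery(contaminated, blood)
        outside = tube & ~ndimage.binary_dilation(brain, iterations=2)
        assert not (out.astype_bool() & outside).any()

    def test_output_subset_of_input(self, rng):
        brain = np.zeros((12, 12, 12), dtype=np.uint8)
        brain[2:10, 2:10, 2:10] = 1
        blood = rng.integers(0, 2, (12, 12, 12)).astype(np.uint8) & brain
        out = trim_brain_mask_periphery(
            BinaryMask(brain, np.eye(4)), BinaryMask(blood, np.eye(4))
        )
        assert not (out.astype_bool() & ~brain.astype(bool)).any()
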