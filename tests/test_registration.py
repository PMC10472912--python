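"""Resampling, transform composition, deformation analysis, and the
affine/nonlinear registration engines."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from bloodless.config import PipelineConfig, fast_config
from bloodless.phantom import PhantomSpec, generate_subject, generate_template
from bloodless.registration import (RegistrationError, affine_from_params,
                                    compose, displacement_magnitude_map,
                                    jacobian_determinant_map,
                                    mutual_information_arrays, register_affine,
                                    register_nonlinear, resample)
from bloodless.types import (AffineTransform, BinaryMask, CompositeTransform,
                             DeformationField, Volume)


def translation(t):
    m = np.eye(4)
    m[:3, 3] = t
    return AffineTransform(m)


class TestResample:
    def test_identity_mask_bit_exact(self, rng):
        mask = BinaryMask(rng.integers(0, 2, (6, 6, 6)).astype(np.uint8), np.eye(4))
        ref = Volume(np.zeros((6, 6, 6)), np.eye(4))
        out = resample(mask, AffineTransform.identity(), ref, "nearest")
        assert np.array_equal(out.data, mask.data)

    def test_integer_shift_moves_delta(self):
        data = np.zeros((8, 8, 8))
        data[3, 3, 3] = 1.0
        v = Volume(data, np.eye(4))
        ref = Volume(np.zeros((8, 8, 8)), np.eye(4))
        # transform maps moving -> fixed: the delta should appear at +1 in x
        out = resample(v, translation((1.0, 0.0, 0.0)), ref, "linear")
        assert out.data[4, 3, 3] == pytest.approx(1.0)
        assert out.data[3, 3, 3] == pytest.approx(0.0)

    def test_linear_on_mask_rejected(self):
        mask = BinaryMask(np.zeros((4, 4, 4), np.uint8), np.eye(4))
        ref = Volume(np.zeros((4, 4, 4)), np.eye(4))
        with pytest.raises(ValueError, match="nearest"):
            resample(mask, AffineTransform.identity(), ref, "linear")

    def test_random_affine_matches_pullback_oracle(self, rng):
        data = rng.random((8, 8, 8))
        v = Volume(data, np.eye(4))
        ref = Volume(np.zeros((8, 8, 8)), np.eye(4))
        m = np.eye(4)
        m[:3, :3] += 0.05 * rng.standard_normal((3, 3))
        m[:3, 3] = rng.uniform(-1, 1, 3)
        t = AffineTransform(m)
        out = resample(v, t, ref, "linear")
        inv = np.linalg.inv(m)

        def trilinear(p):
            p = np.clip(p, 0, 7)
            lo = np.floor(p).astype(int)
            hi = np.minimum(lo + 1, 7)
            f = p - lo
            acc = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        idx = (hi[0] if dx else lo[0],
                               hi[1] if dy else lo[1],
                               hi[2] if dz else lo[2])
                        w = ((f[0] if dx else 1 - f[0])
                             * (f[1] if dy else 1 - f[1])
                             * (f[2] if dz else 1 - f[2]))
                        acc += w * data[idx]
            return acc

        for idx in [(0, 0, 0), (3, 4, 5), (7, 7, 7), (2, 6, 1), (5, 2, 7)]:
            world = np.array(idx, dtype=float)
            p = inv[:3, :3] @ world + inv[:3, 3]
            if np.any(p < 0) or np.any(p > 7):
                continue
            assert out.data[idx] == pytest.approx(trilinear(p), abs=1e-6)


class TestCompose:
    def test_identity_neutral(self):
        t = translation((1.0, 2.0, 3.0))
        comp = compose(AffineTransform.identity(), t)
        assert np.allclose(comp.affine_part.matrix, t.matrix)

    def test_inverse_cancels(self, rng):
        m = np.eye(4)
        m[:3, :3] += 0.1 * rng.standard_normal((3, 3))
        m[:3, 3] = rng.uniform(-3, 3, 3)
        t = AffineTransform(m)
        comp = compose(t, t.inverse())
        pts = rng.uniform(-10, 10, (20, 3))
        out = comp.affine_part.apply_points(pts)
        assert np.max(np.abs(out - pts)) <= 1e-6

    def test_translations_add(self):
        comp = compose(translation((1, 0, 0)), translation((0, 2, 0)))
        assert np.allclose(comp.affine_part.translation, (1, 2, 0))

    def test_composite_second_operand(self):
        field = DeformationField(np.zeros((4, 4, 4, 3)), np.eye(4))
        comp = compose(translation((1, 0, 0)),
                       CompositeTransform(translation((0, 1, 0)), field))
        assert np.allclose(comp.affine_part.translation, (1, 1, 0))
        assert comp.deformation is field

    def test_composite_first_operand_rejected(self):
        c = CompositeTransform.from_affine(AffineTransform.identity())
        with pytest.raises(TypeError):
            compose(c, AffineTransform.identity())


class TestJacobian:
    def test_zero_field_gives_one(self):
        ref = Volume(np.zeros((6, 6, 6)), np.eye(4))
        field = DeformationField(np.zeros((6, 6, 6, 3)), np.eye(4))
        det = jacobian_determinant_map(field, ref)
        assert np.max(np.abs(det.data - 1.0)) <= 1e-6

    def test_uniform_scale_field(self):
        # u(x) = (s-1) x with s = 1.2 -> det = 1.728 in the interior
        shape = (12, 12, 12)
        ref = Volume(np.zeros(shape), np.eye(4))
        coords = np.indices(shape, dtype=float)
        u = np.stack([0.2 * coords[c] for c in range(3)], axis=-1)
        det = jacobian_determinant_map(DeformationField(u, np.eye(4)), ref)
        interior = det.data[1:-1, 1:-1, 1:-1]
        assert np.max(np.abs(interior - 1.728)) <= 1e-3

    def test_matches_explicit_loop_oracle(self, rng):
        shape = (10, 10, 10)
        u = ndimage.gaussian_filter(rng.standard_normal(shape + (3,)), (2, 2, 2, 0))
        ref = Volume(np.zeros(shape), np.eye(4))
        det = jacobian_determinant_map(DeformationField(u, np.eye(4)), ref)

        grads = np.empty(shape + (3, 3))
        for c in range(3):
            g = np.gradient(u[..., c], 1.0, 1.0, 1.0)
            for d in range(3):
                grads[..., c, d] = g[d]
        want = np.empty(shape)
        for idx in np.ndindex(shape):
            j = grads[idx] + np.eye(3)
            want[idx] = abs(np.linalg.det(j))
        assert np.max(np.abs(det.data - want)) <= 1e-6

    def test_affine_only_composite_is_one(self):
        ref = Volume(np.zeros((5, 5, 5)), np.eye(4))
        comp = CompositeTransform.from_affine(translation((3, 0, 0)))
        assert np.all(jacobian_determinant_map(comp, ref).data == 1.0)


class TestDisplacementMagnitude:
    def test_zero_field(self):
        ref = Volume(np.zeros((5, 5, 5)), np.eye(4))
        field = DeformationField(np.zeros((5, 5, 5, 3)), np.eye(4))
        assert np.all(displacement_magnitude_map(field, ref).data == 0.0)

    def test_constant_345_field(self):
        ref = Volume(np.zeros((5, 5, 5)), np.eye(4))
        u = np.zeros((5, 5, 5, 3))
        u[..., 0], u[..., 1] = 3.0, 4.0
        out = displacement_magnitude_map(DeformationField(u, np.eye(4)), ref)
        assert np.all(out.data == 5.0)

    def test_matches_norm_oracle(self, rng):
        u = rng.standard_normal((6, 6, 6, 3))
        ref = Volume(np.zeros((6, 6, 6)), np.eye(4))
        out = displacement_magnitude_map(DeformationField(u, np.eye(4)), ref)
        want = np.sqrt((u**2).sum(axis=-1))
        assert np.max(np.abs(out.data - want)) <= 1e-12


@pytest.fixture(scope="module")
def affine_phantom():
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        noise_sigma=0.0,
        bias_field_amplitude=0.0,
        warp_amplitude_mm=0.0,
        misalign_translation_mm=(3.0, -2.0, 1.0),
        misalign_rotation_deg=(0.0, 0.0, 0.0),
        misalign_scale=(1.0, 1.0, 1.0),
    )
    tpl = generate_template(spec)
    subj = generate_subject(spec, tpl)
    return spec, tpl, subj


class TestAffineRegistration:
    def test_self_registration_is_identity(self, clean_template64, fast_cfg):
        t = register_affine(
            clean_template64.t1, clean_template64.t1,
            clean_template64.brain_mask, None, fast_cfg,
        )
        assert np.max(np.abs(t.translation)) <= 0.1
        # rotation part within 0.1 degree of identity
        r = t.matrix[:3, :3]
        angle = np.degrees(np.arccos(np.clip((np.trace(r / np.cbrt(np.linalg.det(r))) - 1) / 2, -1, 1)))
        assert angle <= 0.1

    def test_known_translation_recovered(self, affine_phantom, fast_cfg):
        spec, tpl, subj = affine_phantom
        t = register_affine(tpl.t1, subj.t1_clean, subj.brain_mask,
                            tpl.brain_mask, fast_cfg)
        err = t.translation - np.array(spec.misalign_translation_mm)
        assert np.max(np.abs(err)) <= 0.5

    def test_deterministic(self, affine_phantom, fast_cfg):
        spec, tpl, subj = affine_phantom
        a = register_affine(tpl.t1, subj.t1_clean, subj.brain_mask, None, fast_cfg)
        b = register_affine(tpl.t1, subj.t1_clean, subj.brain_mask, None, fast_cfg)
        assert np.array_equal(a.matrix, b.matrix)

    def test_empty_fixed_mask_rejected(self, clean_template64, fast_cfg):
        empty = BinaryMask(np.zeros((64, 64, 64), np.uint8),
                           clean_template64.t1.affine)
        with pytest.raises(RegistrationError):
            register_affine(clean_template64.t1, clean_template64.t1, empty,
                            None, fast_cfg)

    def test_cc_metric_also_recovers(self, affine_phantom, fast_cfg):
        spec, tpl, subj = affine_phantom
        t = register_affine(tpl.t1, subj.t1_clean, subj.brain_mask,
                            tpl.brain_mask, fast_cfg, metric="cc")
        err = t.translation - np.array(spec.misalign_translation_mm)
        assert np.max(np.abs(err)) <= 0.5


class TestNonlinearRegistration:
    def test_identical_images_yield_no_deformation(self, clean_template64,
                                                   fast_cfg):
        comp = register_nonlinear(
            clean_template64.t1, clean_template64.t1, AffineTransform.identity(),
            clean_template64.brain_mask, fast_cfg,
        )
        # <= 0.25 voxel everywhere (1 mm voxels)
        assert np.abs(comp.deformation.displacements).max() <= 0.25

    def test_known_warp_recovered_within_1mm(self):
        spec = PhantomSpec(
            grid_shape=(96, 96, 96), noise_sigma=0.0, bias_field_amplitude=0.0,
            warp_amplitude_mm=3.0, misalign_translation_mm=(0, 0, 0),
            misalign_rotation_deg=(0, 0, 0), misalign_scale=(1, 1, 1),
        )
        tpl = generate_template(spec)
        subj = generate_subject(spec, tpl)
        comp = register_nonlinear(
            tpl.t1, subj.t1_clean, AffineTransform.identity(),
            subj.brain_mask, PipelineConfig(),
        )
        u = comp.deformation.displacements
        mask = subj.brain_mask.astype_bool()
        err = np.linalg.norm(u - subj.truth_warp.displacements, axis=-1)[mask]
        assert err.mean() <= 1.0

    def test_mi_never_decreases(self, affine_phantom, fast_cfg):
        spec, tpl, subj = affine_phantom
        init = register_affine(tpl.t1, subj.t1_clean, subj.brain_mask,
                               None, fast_cfg)
        comp = register_nonlinear(tpl.t1, subj.t1_clean, init,
                                  subj.brain_mask, fast_cfg)
        mask = subj.brain_mask.astype_bool()
        before = resample(tpl.t1, init, subj.t1_clean, "linear").data
        after = resample(tpl.t1, comp, subj.t1_clean, "linear").data
        mi0 = mutual_information_arrays(subj.t1_clean.data[mask], before[mask])
        mi1 = mutual_information_arrays(subj.t1_clean.data[mask], after[mask])
        assert mi1 >= mi0

    def test_jacobian_strictly_positive(self, affine_phantom, fast_cfg):
        spec, tpl, subj = affine_phantom
        comp = register_nonlinear(tpl.t1, subj.t1_clean,
                                  subj.truth_affine, subj.brain_mask, fast_cfg)
        ref = Volume(np.zeros(spec.grid_shape), spec.affine)
        det = jacobian_determinant_map(comp, ref)
        assert det.data.min() > 0


class TestParameterisation:
    def test_affine_from_params_translation_only(self):
        t = affine_from_params(np.array([1.0, -2.0, 3.0, 0, 0, 0, 0, 0, 0]),
                               np.zeros(3))
        assert np.allclose(t.translation, (1, -2, 3))
        assert np.allclose(t.matrix[:3, :3], np.eye(3))

    def test_scale_is_log_parameterised(self):
        t = affine_from_params(
            np.array([0, 0, 0, 0, 0, 0, np.log(1.2), 0.0, 0.0]), np.zeros(3)
        )
        assert np.allclose(np.diag(t.matrix[:3, :3]), (1.2, 1.0, 1.0))
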