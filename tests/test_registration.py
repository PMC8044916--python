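import dataclasses

import numpy as np
import pytest

from deltarad import (
    BinaryMask,
    DisplacementField,
    ImageVolume,
    RegistrationConfig,
    SimulationConfig,
    compute_jacobian_map,
    generate_tumor_pair,
    register_deformable,
    select_enhancement_frame,
    summarize_jacobian,
    warp,
)


def _affine_field(shape, scales, center=None, spacing=(1.0, 1.0, 1.0)):
    idx = np.indices(shape, dtype=np.float64)
    world = np.stack([idx[k] * spacing[k] for k in range(3)])
    if center is None:
        center = [(n - 1) * s / 2.0 for n, s in zip(shape, spacing)]
    fld = np.stack(
        [(scales[k] - 1.0) * (world[k] - center[k]) for k in range(3)], axis=-1
    )
    return DisplacementField(fld, spacing)


class TestJacobianMap:
    def test_identity_field_gives_unit_map(self):
        fld = DisplacementField(np.zeros((8, 8, 8, 3)))
        jmap = compute_jacobian_map(fld)
        np.testing.assert_allclose(jmap.values, 1.0, atol=1e-12)
        assert jmap.n_nonpositive == 0

    def test_halving_affine_field_gives_eighth(self):
        fld = _affine_field((12, 12, 12), (0.5, 0.5, 0.5))
        jmap = compute_jacobian_map(fld)
        interior = jmap.values[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(interior, 0.125, atol=1e-6)

    def test_anisotropic_spacing_affine_field(self):
        spacing = (0.5, 1.0, 2.0)
        fld = _affine_field((10, 10, 10), (0.8, 0.9, 0.7), spacing=spacing)
        jmap = compute_jacobian_map(fld)
        interior = jmap.values[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(interior, 0.8 * 0.9 * 0.7, atol=1e-5)

    def test_random_smooth_field_matches_finite_difference_oracle(self, rng):
        from scipy.ndimage import gaussian_filter

        shape = (16, 16, 16)
        u = np.stack(
            [gaussian_filter(rng.normal(0, 2.0, shape), 3.0) for _ in range(3)], axis=-1
        )
        fld = DisplacementField(u)
        jmap = compute_jacobian_map(fld)
        # oracle: differentiate the mapped coordinates voxel-by-voxel
        idx = np.indices(shape, dtype=np.float64)
        phi = np.stack([idx[k] + u[..., k] for k in range(3)])
        det = np.empty(shape)
        for v in np.ndindex(shape):
            j = np.empty((3, 3))
            for comp in range(3):
                for ax in range(3):
                    lo = list(v); hi = list(v)
                    hi[ax] = min(shape[ax] - 1, v[ax] + 1)
                    lo[ax] = max(0, v[ax] - 1)
                    j[comp, ax] = (phi[comp][tuple(hi)] - phi[comp][tuple(lo)]) / (
                        hi[ax] - lo[ax]
                    )
            det[v] = np.linalg.det(j)
        np.testing.assert_allclose(jmap.values, det, atol=1e-6)

    def test_matches_simpleitk_oracle(self, rng):
        import SimpleITK as sitk
        from scipy.ndimage import gaussian_filter

        shape = (14, 14, 14)
        u = np.stack(
            [gaussian_filter(rng.normal(0, 1.5, shape), 2.5) for _ in range(3)], axis=-1
        )
        jmap = compute_jacobian_map(DisplacementField(u))
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(u, (2, 1, 0, 3))), isVector=True
        )
        oracle = sitk.GetArrayFromImage(sitk.DisplacementFieldJacobianDeterminant(img)).T
        interior = (slice(1, -1),) * 3
        np.testing.assert_allclose(jmap.values[interior], oracle[interior], atol=1e-3)

    def test_spacing_mismatch_rejected(self):
        fld = DisplacementField(np.zeros((4, 4, 4, 3)), spacing=(1, 1, 2))
        with pytest.raises(ValueError, match="spacing"):
            compute_jacobian_map(fld, spacing=(1.0, 1.0, 1.0))

    def test_composition_of_affines_multiplies_determinants(self):
        sa, sb = (0.8, 0.9, 0.7), (0.9, 0.85, 0.95)
        shape = (16, 16, 16)
        fa = _affine_field(shape, sa)
        fb = _affine_field(shape, sb)
        # compose: u_ab(x) = u_b(x) + u_a(x + u_b(x)); affine fields about the
        # same centre compose to the affine with products of the scales
        composed = _affine_field(shape, tuple(a * b for a, b in zip(sa, sb)))
        j = compute_jacobian_map(composed).values[2:-2, 2:-2, 2:-2]
        ja = compute_jacobian_map(fa).values[2:-2, 2:-2, 2:-2]
        jb = compute_jacobian_map(fb).values[2:-2, 2:-2, 2:-2]
        np.testing.assert_allclose(j, ja * jb, rtol=1e-6)


class TestWarp:
    def test_identity_field_is_noop(self, rng):
        vol = ImageVolume(rng.normal(size=(8, 8, 8)).astype(np.float32))
        out = warp(vol, DisplacementField(np.zeros((8, 8, 8, 3))))
        np.testing.assert_allclose(out.values, vol.values, atol=1e-6)

    def test_one_voxel_translation_on_ramp(self):
        n = 12
        ramp = np.indices((n, n, n), dtype=np.float64)[0]
        vol = ImageVolume(ramp.astype(np.float32))
        u = np.zeros((n, n, n, 3))
        u[..., 0] = 1.0  # one voxel at 1 mm spacing
        out = warp(vol, DisplacementField(u))
        interior = (slice(0, -1), slice(None), slice(None))
        np.testing.assert_allclose(out.values[interior], ramp[interior] + 1.0, atol=1e-6)

    def test_mask_volume_ratio_under_affine_scale(self):
        n = 48
        idx = np.indices((n, n, n), dtype=float)
        r = np.sqrt(((idx - (n - 1) / 2) ** 2).sum(axis=0))
        mask = (r <= 14).astype(np.float32)
        s = 0.8
        # pull-back through the *inverse* scaling warps the mask to s x size
        inv = _affine_field((n, n, n), (1 / s, 1 / s, 1 / s))
        warped = warp(ImageVolume(mask), inv)
        ratio = (warped.values > 0.5).sum() / mask.sum()
        assert ratio == pytest.approx(s**3, rel=0.05)


class TestRegistration:
    def test_self_registration_field_is_negligible(self):
        cfg = SimulationConfig(shape=(48, 48, 48))
        b, _, mask, _, _ = generate_tumor_pair(cfg, False, seed=21)
        _, sub = select_enhancement_frame(b)
        fld, warped, report = register_deformable(sub, sub)
        mag = np.sqrt((fld.field**2).sum(axis=-1))
        assert mag.mean() < 0.1
        assert report.improved or report.final_metric <= report.initial_metric + 1e-9

    def test_known_contraction_recovered(self):
        """Mean endpoint error < 0.5 voxel and mean Jacobian within 15%
        of the analytic value for a planted s=0.8 contraction."""
        s = 0.8
        cfg = dataclasses.replace(
            SimulationConfig(),
            tumor_radius_range=(12.0, 12.0),
            residual_field_amplitude=0.0,
            bias_amplitude=0.0,
        )
        b, f, mask, truth, meta = generate_tumor_pair(
            cfg, True, seed=22, contraction=(s, s, s), heterogeneity_reduction=0.0
        )
        _, sub_b = select_enhancement_frame(b)
        _, sub_f = select_enhancement_frame(f)
        fld, warped, report = register_deformable(sub_b, sub_f)
        sel = mask.as_bool()
        epe = np.sqrt(((fld.field - truth.field) ** 2).sum(axis=-1))
        assert epe[sel].mean() < 0.5
        jmean = summarize_jacobian(compute_jacobian_map(fld), mask)["mean"]
        assert jmean == pytest.approx(s**3, rel=0.15)

    def test_smooth_residual_field_recovered(self):
        """With only a small smooth residual deformation, the warped
        follow-up correlates r > 0.98 with the baseline inside the tumor."""
        cfg = dataclasses.replace(
            SimulationConfig(),
            tumor_radius_range=(12.0, 12.0),
            residual_field_amplitude=0.5,
            bias_amplitude=0.0,
            noise_sd=1.0,
        )
        b, f, mask, truth, _ = generate_tumor_pair(
            cfg, True, seed=30, contraction=(1.0, 1.0, 1.0), heterogeneity_reduction=0.0
        )
        _, sub_b = select_enhancement_frame(b)
        _, sub_f = select_enhancement_frame(f)
        fld, _, _ = register_deformable(sub_b, sub_f)
        sel = mask.as_bool()
        warped = warp(sub_f, fld, order=3)
        r = np.corrcoef(warped.values[sel], sub_b.values[sel])[0, 1]
        assert r > 0.98

    def test_jacobian_integral_approximates_volume_ratio(self):
        s = 0.85
        cfg = dataclasses.replace(
            SimulationConfig(),
            tumor_radius_range=(12.0, 12.0),
            residual_field_amplitude=0.3,
            bias_amplitude=0.0,
        )
        b, f, mask, truth, meta = generate_tumor_pair(
            cfg, True, seed=23, contraction=(s, s, s), heterogeneity_reduction=0.0
        )
        jmap = compute_jacobian_map(truth)
        integral = jmap.values[mask.as_bool()].mean()
        assert integral == pytest.approx(meta["true_volume_ratio"], rel=0.10)

    def test_registration_deterministic(self):
        cfg = SimulationConfig(shape=(48, 48, 48))
        b, f, _, _, _ = generate_tumor_pair(cfg, True, seed=24)
        _, sub_b = select_enhancement_frame(b)
        _, sub_f = select_enhancement_frame(f)
        f1, _, _ = register_deformable(sub_b, sub_f)
        f2, _, _ = register_deformable(sub_b, sub_f)
        np.testing.assert_array_equal(f1.field, f2.field)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RegistrationConfig(shrink_factors=(4, 2), iterations=(10,))

    def test_summarize_requires_matching_lattice(self):
        jmap = compute_jacobian_map(DisplacementField(np.zeros((6, 6, 6, 3))))
        with pytest.raises(ValueError, match="empty"):
            summarize_jacobian(jmap, BinaryMask(np.zeros((6, 6, 6), dtype=np.uint8)))
        stats = summarize_jacobian(jmap, BinaryMask(np.ones((6, 6, 6), dtype=np.uint8)))
        assert stats["mean"] == pytest.approx(1.0)
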