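import numpy as np
import pytest

from sctdir.core import DisplacementField, ImageGrid, VelocityField
from sctdir.demons import (
    DemonsConfig,
    compose_displacements,
    demons_energy,
    demons_update,
    exp_velocity,
    register_diffeodemons,
    warp_image,
    warp_structures,
)
from sctdir.phantom import (
    PhantomConfig, generate_phantom, jacobian_determinant, sample_smooth_deformation,
)


def ramp_image(n=32, spacing=(1.0, 1.0)):
    vals = np.arange(n, dtype=float)[:, None] * np.ones(n)[None, :]
    return ImageGrid(vals, spacing)


class TestWarpImage:
    def test_zero_dvf_identity(self, phantom_64):
        img, _ = phantom_64
        dvf = DisplacementField.zeros(img.shape, img.spacing)
        out = warp_image(img, dvf, "linear")
        np.testing.assert_allclose(out.values, img.values, atol=1e-9)

    def test_constant_shift_on_ramp(self):
        img = ramp_image(32)
        u = np.zeros((32, 32, 2))
        u[..., 0] = 1.0  # +1 mm = +1 voxel along axis 0
        out = warp_image(img, DisplacementField(u, (1.0, 1.0)), "linear")
        # output(x) = input(x + 1): interior rows shift down by one ramp step
        np.testing.assert_allclose(out.values[:-1], img.values[1:], atol=1e-9)

    def test_spacing_aware_shift(self):
        img = ramp_image(32, spacing=(2.0, 1.0))
        u = np.zeros((32, 32, 2))
        u[..., 0] = 2.0  # 2 mm = 1 voxel at 2 mm spacing
        out = warp_image(img, DisplacementField(u, (2.0, 1.0)), "linear")
        np.testing.assert_allclose(out.values[:-1], img.values[1:], atol=1e-9)

    def test_nearest_keeps_masks_binary(self, phantom_64):
        img, st = phantom_64
        f = sample_smooth_deformation(img.shape, img.spacing, 3.0, 15.0, seed=1)
        warped = warp_structures(st, f)
        for name in warped.names:
            assert set(np.unique(warped[name])) <= {0, 1}

    def test_grid_mismatch_raises(self, phantom_64):
        img, _ = phantom_64
        dvf = DisplacementField.zeros((16, 16), (1.0, 1.0))
        with pytest.raises(ValueError, match="mismatch"):
            warp_image(img, dvf)

    def test_invalid_interpolation(self, phantom_64):
        img, _ = phantom_64
        dvf = DisplacementField.zeros(img.shape, img.spacing)
        with pytest.raises(ValueError):
            warp_image(img, dvf, "spline")


class TestDemonsEnergy:
    def test_identity_zero(self, phantom_64):
        img, _ = phantom_64
        dvf = DisplacementField.zeros(img.shape, img.spacing)
        assert demons_energy(img, img, dvf, 1.0) == 0.0

    def test_zero_displacement_is_plain_ssd(self, phantom_64, rng):
        img, _ = phantom_64
        other = img.with_values(img.values + rng.standard_normal(img.shape))
        dvf = DisplacementField.zeros(img.shape, img.spacing)
        expected = float(np.sum((img.values - other.values) ** 2))  # brute-force SSD
        assert demons_energy(img, other, dvf, 5.0) == pytest.approx(expected, rel=1e-12)

    def test_quadratic_scaling(self, phantom_64):
        img, _ = phantom_64
        dvf = DisplacementField.zeros(img.shape, img.spacing)
        e1 = demons_energy(img, img.with_values(img.values + 1.0), dvf, 0.0)
        e2 = demons_energy(img, img.with_values(img.values + 2.0), dvf, 0.0)
        assert e2 == pytest.approx(4 * e1, rel=1e-12)

    def test_lambda_zero_ignores_smoothness(self, phantom_64, rng):
        img, _ = phantom_64
        rough = rng.standard_normal(img.shape + (2,))
        dvf = DisplacementField(rough * 0.0, img.spacing)
        bumpy = DisplacementField(rough * 1e-9, img.spacing)
        e_flat = demons_energy(img, img, dvf, 0.0)
        e_bump = demons_energy(img, img, bumpy, 0.0)
        assert e_flat == pytest.approx(0.0, abs=1e-9)
        assert e_bump == pytest.approx(e_flat, abs=1e-6)

    def test_regularizer_penalizes_gradients(self, phantom_64):
        img, _ = phantom_64
        u = np.zeros(img.shape + (2,))
        u[..., 0] = np.linspace(0, 1, img.shape[0])[:, None]
        dvf = DisplacementField(u, img.spacing)
        e0 = demons_energy(img, img, dvf, 0.0)
        e1 = demons_energy(img, img, dvf, 1.0)
        assert e1 > e0

    def test_grid_mismatch(self, phantom_64):
        img, _ = phantom_64
        small = ImageGrid(np.zeros((8, 8)), (1, 1))
        dvf = DisplacementField.zeros(img.shape, img.spacing)
        with pytest.raises(ValueError):
            demons_energy(img, small, dvf, 1.0)


class TestExpVelocity:
    def test_zero_velocity(self):
        v = VelocityField.zeros((16, 16), (1.0, 1.0))
        u = exp_velocity(v, 6)
        np.testing.assert_array_equal(u.vectors, 0.0)

    def test_constant_velocity_is_translation(self):
        vec = np.zeros((32, 32, 2))
        vec[..., 0] = 1.5
        vec[..., 1] = -0.5
        u = exp_velocity(VelocityField(vec, (1.0, 1.0)), 6)
        interior = (slice(6, -6), slice(6, -6))
        np.testing.assert_allclose(u.vectors[interior + (0,)], 1.5, atol=1e-6)
        np.testing.assert_allclose(u.vectors[interior + (1,)], -0.5, atol=1e-6)

    def test_linear_field_matches_matrix_exponential(self):
        from scipy.linalg import expm

        n = 32
        A = np.array([[0.08, 0.03], [-0.02, 0.05]])
        x0 = np.array([(n - 1) / 2.0] * 2)
        idx = np.stack(np.meshgrid(np.arange(n), np.arange(n), indexing="ij"), -1).astype(float)
        v = (idx - x0) @ A.T
        exact = (idx - x0) @ (expm(A) - np.eye(2)).T
        interior = (slice(6, -6), slice(6, -6))
        u = exp_velocity(VelocityField(v, (1.0, 1.0)), 8)
        err = np.abs(u.vectors - exact)[interior].max()
        assert err < 0.05

    def test_error_decreases_with_squaring_steps(self):
        from scipy.linalg import expm

        n = 32
        A = np.array([[0.1, -0.04], [0.05, 0.07]])
        x0 = np.array([(n - 1) / 2.0] * 2)
        idx = np.stack(np.meshgrid(np.arange(n), np.arange(n), indexing="ij"), -1).astype(float)
        v = (idx - x0) @ A.T
        exact = (idx - x0) @ (expm(A) - np.eye(2)).T
        interior = (slice(6, -6), slice(6, -6))
        errs = []
        for k in (1, 3, 5, 8):
            u = exp_velocity(VelocityField(v, (1.0, 1.0)), k)
            errs.append(np.abs(u.vectors - exact)[interior].max())
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_negative_steps_rejected(self):
        v = VelocityField.zeros((8, 8), (1.0, 1.0))
        with pytest.raises(ValueError):
            exp_velocity(v, -1)


class TestComposeDisplacements:
    def test_compose_with_zero(self, rng):
        u = sample_smooth_deformation((24, 24), (1.0, 1.0), 2.0, 8.0, seed=3)
        zero = DisplacementField.zeros((24, 24), (1.0, 1.0))
        out = compose_displacements(u, zero)
        np.testing.assert_allclose(out.vectors, u.vectors, atol=1e-9)

    def test_constant_shifts_add(self):
        a = np.zeros((24, 24, 2))
        a[..., 0] = 1.0
        b = np.zeros((24, 24, 2))
        b[..., 1] = 2.0
        out = compose_displacements(
            DisplacementField(a, (1.0, 1.0)), DisplacementField(b, (1.0, 1.0)))
        interior = (slice(4, -4), slice(4, -4))
        np.testing.assert_allclose(out.vectors[interior][..., 0], 1.0, atol=1e-9)
        np.testing.assert_allclose(out.vectors[interior][..., 1], 2.0, atol=1e-9)


class TestDemonsUpdate:
    def test_converged_zero_increment(self, phantom_64):
        img, _ = phantom_64
        zero = DisplacementField.zeros(img.shape, img.spacing)
        dv = demons_update(img, img, zero, DemonsConfig())
        np.testing.assert_allclose(dv.vectors, 0.0, atol=1e-12)

    def test_step_bound_cap(self, phantom_64, rng):
        img, _ = phantom_64
        noisy = img.with_values(img.values + 500 * rng.standard_normal(img.shape))
        zero = DisplacementField.zeros(img.shape, img.spacing)
        cfg = DemonsConfig(step_bound_mm=1.5, sigma_fluid_mm=0.0)
        dv = demons_update(img, noisy, zero, cfg)
        assert np.sqrt((dv.vectors**2).sum(-1)).max() <= 1.5 + 1e-9

    def test_update_descends_ssd(self, phantom_64):
        # the raw force is a descent direction for the SSD term
        img, _ = phantom_64
        f = sample_smooth_deformation(img.shape, img.spacing, 2.0, 20.0, seed=5)
        fixed = warp_image(img, f, "linear")
        zero = DisplacementField.zeros(img.shape, img.spacing)
        cfg = DemonsConfig(sigma_fluid_mm=1.0, step_bound_mm=2.0)
        dv = demons_update(img, fixed, zero, cfg)
        ssd0 = float(np.sum((img.values - fixed.values) ** 2))
        for eps in (0.01, 0.05, 0.25):  # small steps: local descent direction
            stepped = DisplacementField(eps * dv.vectors, img.spacing)
            ssd = float(np.sum((warp_image(img, stepped).values - fixed.values) ** 2))
            assert ssd < ssd0


class TestRegister:
    def test_self_registration_near_identity(self, phantom_64):
        img, _ = phantom_64
        dvf, diag = register_diffeodemons(img, img, DemonsConfig(levels=2, iterations_per_level=10))
        assert np.abs(dvf.vectors).max() < 0.1  # voxels == mm here

    def test_recovery_of_known_deformation(self, phantom_128):
        img, st = phantom_128
        gt = sample_smooth_deformation(img.shape, img.spacing, 3.0, 20.0, seed=7)
        fixed = warp_image(img, gt, "linear")
        dvf, diag = register_diffeodemons(fixed, img, DemonsConfig())
        ssd0 = float(np.sum((img.values - fixed.values) ** 2))
        ssd1 = float(np.sum((warp_image(img, dvf).values - fixed.values) ** 2))
        assert ssd1 <= 0.10 * ssd0
        body = st["body"] > 0
        err = np.sqrt(((dvf.vectors - gt.vectors) ** 2).sum(-1))
        assert err[body].mean() <= 1.0  # <= 1 voxel at 1 mm spacing
        assert diag["min_jacobian"] > 0

    def test_jacobian_positive_default_settings(self, phantom_64):
        img, _ = phantom_64
        gt = sample_smooth_deformation(img.shape, img.spacing, 3.0, 15.0, seed=11)
        fixed = warp_image(img, gt, "linear")
        dvf, diag = register_diffeodemons(fixed, img, DemonsConfig(levels=2))
        assert jacobian_determinant(dvf).min() > 0

    def test_energy_trace_non_increasing_with_reject(self, phantom_64):
        img, _ = phantom_64
        gt = sample_smooth_deformation(img.shape, img.spacing, 2.0, 15.0, seed=2)
        fixed = warp_image(img, gt, "linear")
        cfg = DemonsConfig(levels=2, iterations_per_level=15, reject_worsening=True)
        _, diag = register_diffeodemons(fixed, img, cfg)
        for trace in diag["energy_traces"]:
            assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_grid_mismatch_raises(self, phantom_64):
        img, _ = phantom_64
        other = ImageGrid(img.values, (2.0, 2.0))
        with pytest.raises(ValueError, match="grid"):
            register_diffeodemons(img, other)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DemonsConfig(iterations_per_level=0)
        with pytest.raises(ValueError):
            DemonsConfig(regularization_weight=-1)
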