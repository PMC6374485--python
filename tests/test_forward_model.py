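"""Image-formation operators: T, H, their adjoints, background and PSF."""

import numpy as np
import pytest

from matirf import (
    AcquisitionStack,
    AngleSet,
    BackgroundModel,
    ExcitationModel,
    GridSpec,
    OpticalConfig,
    PSFModel,
    apply_H,
    apply_H_adjoint,
    apply_T,
    apply_T_adjoint,
    build_tirf_matrix,
    estimate_background,
    forward,
    make_psf,
)
from matirf.forward_model import DimensionError
from matirf.optics import ConfigurationError


def widefield_excitation(m=3):
    """Excitation with p so small that exp(-z p) == 1.0 in float arithmetic."""
    angles = AngleSet(tuple(63.0 + i for i in range(m)))
    p = 1e-300 * (1 + np.arange(m))
    return ExcitationModel(angle_set=angles, i0=np.ones(m), p=p)


class TestTirfMatrix:
    def test_brute_force_oracle(self, excitation, small_grid):
        tz = build_tirf_matrix(excitation, small_grid)
        for m in range(excitation.n_angles):
            for j in range(small_grid.nz):
                z = small_grid.z0_nm + j * small_grid.dz_nm
                expected = excitation.i0[m] * np.exp(-z * excitation.p[m]) \
                    * small_grid.dz_nm
                assert tz[m, j] == pytest.approx(expected, rel=1e-14)

    def test_rows_positive_and_decreasing(self, excitation):
        grid = GridSpec(nx=2, ny=2, nz=10, dz_nm=20.0)
        tz = build_tirf_matrix(excitation, grid)
        assert np.all(tz > 0)
        assert np.all(np.diff(tz, axis=1) < 0)

    def test_widefield_limit_rows_constant(self):
        exc = widefield_excitation()
        grid = GridSpec(nx=2, ny=2, nz=5, dz_nm=20.0)
        tz = build_tirf_matrix(exc, grid)
        assert np.all(tz == exc.i0[:, None] * grid.dz_nm)

    def test_penetration_depth_entry(self, excitation):
        # slice center placed exactly at 1/p for angle 0 => entry I0 * dz / e
        depth = 1.0 / excitation.p[0]
        grid = GridSpec(nx=1, ny=1, nz=2, dz_nm=depth, z0_nm=0.0)
        tz = build_tirf_matrix(excitation, grid)
        assert tz[0, 1] == pytest.approx(
            excitation.i0[0] * grid.dz_nm / np.e, rel=1e-12)

    def test_exact_quadrature_close_to_midpoint(self, excitation):
        # slabs fully inside the sample: midpoint error is O((p dz)^2 / 24),
        # below 0.5% for p <= 1/60 nm^-1 and dz = 20 nm
        grid = GridSpec(nx=2, ny=2, nz=4, dz_nm=20.0, z0_nm=10.0)
        mid = build_tirf_matrix(excitation, grid, quadrature="midpoint")
        exact = build_tirf_matrix(excitation, grid, quadrature="exact")
        assert np.allclose(mid, exact, rtol=6e-3)


class TestApplyT:
    def test_impulse(self, excitation, small_grid):
        tz = build_tirf_matrix(excitation, small_grid)
        f = np.zeros(small_grid.shape)
        f[1, 2, 3] = 1.0
        out = apply_T(tz, f)
        for m in range(tz.shape[0]):
            assert out[m, 2, 3] == tz[m, 1]
        out[:, 2, 3] = 0
        assert np.all(out == 0)

    def test_zero_volume(self, excitation, small_grid):
        tz = build_tirf_matrix(excitation, small_grid)
        assert np.all(apply_T(tz, np.zeros(small_grid.shape)) == 0)

    def test_brute_force_oracle(self, rng, excitation, small_grid):
        tz = build_tirf_matrix(excitation, small_grid)[:2]
        f = rng.random(small_grid.shape)
        out = apply_T(tz, f)
        for m in range(2):
            for iy in range(small_grid.ny):
                for ix in range(small_grid.nx):
                    expected = sum(tz[m, j] * f[j, iy, ix]
                                   for j in range(small_grid.nz))
                    assert out[m, iy, ix] == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch(self, excitation, small_grid):
        tz = build_tirf_matrix(excitation, small_grid)
        with pytest.raises(DimensionError):
            apply_T(tz, np.zeros((small_grid.nz + 1, 4, 4)))


class TestAdjoints:
    def test_T_adjoint_identity(self, rng, excitation, small_grid):
        tz = build_tirf_matrix(excitation, small_grid)
        f = rng.random(small_grid.shape)
        g = rng.random((tz.shape[0],) + small_grid.shape[1:])
        lhs = float((apply_T(tz, f) * g).sum())
        rhs = float((f * apply_T_adjoint(tz, g)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_T_adjoint_matches_dense_transpose(self, rng, excitation, small_grid):
        tz = build_tirf_matrix(excitation, small_grid)
        g = rng.random((tz.shape[0],) + small_grid.shape[1:])
        out = apply_T_adjoint(tz, g)
        # dense oracle on vectorized per-pixel profiles
        for iy in range(small_grid.ny):
            for ix in range(small_grid.nx):
                assert np.allclose(out[:, iy, ix], tz.T @ g[:, iy, ix],
                                   rtol=1e-12)

    def test_H_adjoint_identity(self, rng):
        psf = PSFModel(kernel=np.array([[0.0, 1, 0], [1, 4, 1], [0, 1, 0.0]]))
        a = rng.random((4, 8, 8))
        b = rng.random((4, 8, 8))
        lhs = float((apply_H(a, psf) * b).sum())
        rhs = float((a * apply_H_adjoint(b, psf)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_TH_composition_adjoint(self, rng, excitation):
        grid = GridSpec(nx=8, ny=8, nz=4)
        tz = build_tirf_matrix(excitation, grid)
        psf = make_psf(OpticalConfig(), provenance="gaussian", size=3)
        f = rng.random(grid.shape)
        g = rng.random((tz.shape[0], 8, 8))
        lhs = float((apply_T(tz, apply_H(f, psf)) * g).sum())
        rhs = float((f * apply_H_adjoint(apply_T_adjoint(tz, g), psf)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestApplyH:
    def test_delta_identity(self, rng):
        vol = rng.random((3, 6, 6))
        psf = PSFModel(kernel=np.ones((1, 1)))
        assert np.array_equal(apply_H(vol, psf), vol)

    def test_dc_preserved_in_interior(self):
        # away from the zero-padded border a normalized kernel keeps constants
        psf = PSFModel(kernel=np.ones((3, 3)))
        vol = np.full((2, 8, 8), 5.0)
        out = apply_H(vol, psf)
        assert np.allclose(out[:, 1:-1, 1:-1], 5.0, rtol=1e-12)

    def test_brute_force_zero_boundary_oracle(self, rng):
        k = rng.random((3, 3))
        psf = PSFModel(kernel=k)
        kn = psf.kernel
        s = rng.random((8, 8))
        out = apply_H(s, psf)
        padded = np.zeros((10, 10))
        padded[1:9, 1:9] = s
        for iy in range(8):
            for ix in range(8):
                acc = 0.0
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        acc += kn[1 + dy, 1 + dx] * padded[1 + iy - dy, 1 + ix - dx]
                assert out[iy, ix] == pytest.approx(acc, abs=1e-12)


class TestForward:
    def test_background_only(self, excitation, small_grid):
        tz = build_tirf_matrix(excitation, small_grid)
        psf = PSFModel(kernel=np.ones((1, 1)))
        b = BackgroundModel(np.full(excitation.n_angles, 3.5))
        out = forward(np.zeros(small_grid.shape), tz, psf, b)
        assert np.all(out == 3.5)

    def test_delta_psf_reduces_to_T(self, rng, excitation, small_grid):
        tz = build_tirf_matrix(excitation, small_grid)
        psf = PSFModel(kernel=np.ones((1, 1)))
        f = rng.random(small_grid.shape)
        b = BackgroundModel.zero(excitation.n_angles)
        assert np.allclose(forward(f, tz, psf, b), apply_T(tz, f))

    def test_composed_oracle(self, rng, excitation):
        grid = GridSpec(nx=6, ny=6, nz=3)
        tz = build_tirf_matrix(excitation, grid)
        psf = make_psf(OpticalConfig(), provenance="gaussian", size=3)
        f = rng.random(grid.shape)
        b = BackgroundModel(rng.random(excitation.n_angles))
        out = forward(f, tz, psf, b)
        expected = apply_T(tz, apply_H(f, psf)) + b.level_per_angle[:, None, None]
        assert np.allclose(out, expected, rtol=1e-12)

    def test_positivity_preserved(self, rng, excitation, small_grid):
        tz = build_tirf_matrix(excitation, small_grid)
        psf = make_psf(OpticalConfig(), provenance="gaussian", size=3)
        f = rng.random(small_grid.shape)
        b = BackgroundModel(rng.random(excitation.n_angles))
        assert np.all(forward(f, tz, psf, b) >= 0)

    def test_widefield_consistency(self):
        # p -> 0 and delta PSF: every angle image is dz * axial sum + b
        exc = widefield_excitation()
        grid = GridSpec(nx=5, ny=4, nz=6, dz_nm=20.0)
        f = np.random.default_rng(0).random(grid.shape)
        psf = PSFModel(kernel=np.ones((1, 1)))
        b = BackgroundModel(np.full(3, 0.25))
        out = forward(f, build_tirf_matrix(exc, grid), psf, b)
        expected = grid.dz_nm * f.sum(axis=0) + 0.25
        assert np.allclose(out, expected[None], rtol=1e-12)

    def test_energy_decreases_with_angle(self, excitation):
        # mass at depth: steeper angles excite it less
        grid = GridSpec(nx=3, ny=3, nz=10, dz_nm=20.0)
        f = np.zeros(grid.shape)
        f[6] = 1.0  # 120 nm deep
        tz = build_tirf_matrix(excitation, grid)
        psf = PSFModel(kernel=np.ones((1, 1)))
        totals = forward(f, tz, psf, BackgroundModel.zero(4)).sum(axis=(1, 2))
        assert np.all(np.diff(totals) < 0)


class TestBackgroundEstimation:
    def test_constant_value(self, excitation):
        imgs = np.full((4, 5, 5), 7.0)
        stack = AcquisitionStack(images=imgs, angle_set=excitation.angle_set)
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, :2] = True
        bg = estimate_background(stack, mask)
        assert np.all(bg.level_per_angle == 7.0)

    def test_two_pixel_mean(self, excitation):
        imgs = np.zeros((4, 2, 2))
        imgs[:, 0, 0] = 1.0
        imgs[:, 0, 1] = 3.0
        stack = AcquisitionStack(images=imgs, angle_set=excitation.angle_set)
        mask = np.array([[True, True], [False, False]])
        assert np.all(estimate_background(stack, mask).level_per_angle == 2.0)

    def test_random_oracle(self, rng, excitation):
        imgs = rng.random((4, 6, 6))
        stack = AcquisitionStack(images=imgs, angle_set=excitation.angle_set)
        mask = rng.random((6, 6)) > 0.5
        bg = estimate_background(stack, mask)
        for m in range(4):
            assert bg.level_per_angle[m] == pytest.approx(
                imgs[m][mask].mean(), rel=1e-14)

    def test_empty_mask(self, excitation):
        imgs = np.zeros((4, 3, 3))
        stack = AcquisitionStack(images=imgs, angle_set=excitation.angle_set)
        with pytest.raises(ConfigurationError):
            estimate_background(stack, np.zeros((3, 3), dtype=bool))


class TestMakePsf:
    def test_gaussian_width(self):
        # sigma = 0.21 * 491 / 1.49 / 107 ~ 0.647 px
        cfg = OpticalConfig()
        psf = make_psf(cfg, provenance="gaussian")
        k = psf.kernel
        iy, ix = np.indices(k.shape)
        cx = (k.shape[1] - 1) / 2
        var = float((k * (ix - cx) ** 2).sum())
        assert np.sqrt(var) == pytest.approx(0.647, abs=0.01)

    def test_rotation_symmetry_and_normalization(self):
        for prov in ("gaussian", "airy"):
            psf = make_psf(OpticalConfig(), provenance=prov, size=9)
            assert psf.kernel.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(psf.kernel, np.rot90(psf.kernel), atol=1e-14)

    def test_zero_user_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            make_psf(OpticalConfig(), provenance="user_supplied",
                     kernel=np.zeros((3, 3)))
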