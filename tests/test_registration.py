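"""Elastic registration: similarity, operators, linear solve, pairwise solver."""

import numpy as np
import pytest

from cardiomoco import (
    DisplacementField,
    RegistrationParams,
    ScalarVolume,
    VolumeGrid,
    elastic_energy,
    elastic_operator_apply,
    force_vector,
    register_pair,
    solve_displacement_update,
    ssd_similarity,
)
from cardiomoco.registration import (
    _stabilized_operator,
    _tikhonov_eps,
    lame_from_elastic_moduli,
)


def dense_navier_lame_matrix(grid: VolumeGrid, params: RegistrationParams) -> np.ndarray:
    """Independent dense assembly of mu*Lap + (mu+lambda)*grad(div).

    Explicit index loops with the same stencil conventions: second-order
    central differences and edge-replicated (Neumann) ghost values, each
    axis clamped independently.
    """
    nx, ny, nz = grid.shape
    h = grid.spacing
    mu, lam = params.lame_mu, params.lame_lambda
    n = nx * ny * nz * 3

    def flat(i, j, k, c):
        return ((i * ny + j) * nz + k) * 3 + c

    def clamp(v, n_ax):
        return min(max(v, 0), n_ax - 1)

    A = np.zeros((n, n))
    shape = (nx, ny, nz)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                idx = (i, j, k)
                for c in range(3):
                    row = flat(i, j, k, c)
                    # Laplacian of component c
                    for ax in range(3):
                        for off in (-1, 1):
                            nb = list(idx)
                            nb[ax] = clamp(nb[ax] + off, shape[ax])
                            A[row, flat(*nb, c)] += mu / h[ax] ** 2
                        A[row, flat(i, j, k, c)] += -2.0 * mu / h[ax] ** 2
                    # grad(div): d_c d_m u_m
                    for m in range(3):
                        if m == c:
                            for off in (-1, 1):
                                nb = list(idx)
                                nb[m] = clamp(nb[m] + off, shape[m])
                                A[row, flat(*nb, m)] += (mu + lam) / h[m] ** 2
                            A[row, flat(i, j, k, m)] += -2.0 * (mu + lam) / h[m] ** 2
                        else:
                            for o1 in (-1, 1):
                                for o2 in (-1, 1):
                                    nb = list(idx)
                                    nb[c] = clamp(nb[c] + o1, shape[c])
                                    nb[m] = clamp(nb[m] + o2, shape[m])
                                    A[row, flat(*nb, m)] += (
                                        o1 * o2 * (mu + lam) / (4.0 * h[c] * h[m])
                                    )
    return A


class TestSSD:
    def test_identity_is_zero(self, unit_grid):
        rng = np.random.default_rng(0)
        vol = ScalarVolume(unit_grid, rng.normal(size=(8, 8, 8)))
        zero = DisplacementField.zero(unit_grid)
        assert ssd_similarity(vol, vol, zero) == 0.0

    def test_exact_shift_compensation_on_constant_background(self):
        # blob on constant background, shifted by one voxel along x; a
        # uniform displacement of one voxel spacing cancels the SSD exactly
        grid = VolumeGrid((12, 8, 8), (2.0, 1.0, 1.0))
        base = np.zeros((12, 8, 8))
        base[5, 4, 4] = 100.0
        ref = np.zeros((12, 8, 8))
        ref[4, 4, 4] = 100.0  # template shifted by -1 voxel => u = -2 mm? no:
        # reference(x) = template(x + u) with u = +? template has blob at 5,
        # reference at 4: template(x + (+2mm,0,0)) puts blob at 4. u = +2mm.
        u = np.zeros((12, 8, 8, 3))
        u[..., 0] = 2.0
        field = DisplacementField(grid, u)
        assert ssd_similarity(
            ScalarVolume(grid, ref), ScalarVolume(grid, base), field
        ) == pytest.approx(0.0, abs=1e-18)

    def test_hand_summed_residuals_1d_toy(self):
        grid = VolumeGrid((4, 2, 2), (1.0, 1.0, 1.0))
        ref = np.zeros((4, 2, 2))
        tpl = np.zeros((4, 2, 2))
        ref[2, 0, 0] = 1.0
        tpl[1, 0, 0] = 1.0
        zero = DisplacementField.zero(grid)
        # residuals are +-1 at two voxels: 0.5 * 2 * voxel volume
        assert ssd_similarity(
            ScalarVolume(grid, ref), ScalarVolume(grid, tpl), zero
        ) == pytest.approx(1.0)

    def test_invariant_under_common_intensity_offset(self, unit_grid):
        rng = np.random.default_rng(1)
        r = rng.normal(size=(8, 8, 8))
        t = rng.normal(size=(8, 8, 8))
        u = DisplacementField(unit_grid, 0.3 * rng.normal(size=(8, 8, 8, 3)))
        s1 = ssd_similarity(ScalarVolume(unit_grid, r), ScalarVolume(unit_grid, t), u)
        s2 = ssd_similarity(
            ScalarVolume(unit_grid, r + 250.0), ScalarVolume(unit_grid, t + 250.0), u
        )
        assert s1 == pytest.approx(s2, rel=1e-9)


class TestElasticEnergy:
    def test_zero_and_translation_have_zero_energy(self, aniso_grid):
        params = RegistrationParams()
        assert elastic_energy(DisplacementField.zero(aniso_grid), params) == 0.0
        const = np.ones(aniso_grid.shape + (3,)) * [1.0, -2.0, 0.5]
        assert elastic_energy(DisplacementField(aniso_grid, const), params) == 0.0

    def test_uniform_strain_closed_form(self):
        # u = (alpha*x, 0, 0): energy density mu*alpha^2 + lambda/2*alpha^2
        grid = VolumeGrid((16, 16, 16), (1.0, 1.0, 1.0))
        params = RegistrationParams(lame_mu=1.3, lame_lambda=0.8)
        alpha = 0.05
        x = np.arange(16, dtype=float)[:, None, None]
        u = np.zeros((16, 16, 16, 3))
        u[..., 0] = alpha * np.broadcast_to(x, (16, 16, 16))
        got = elastic_energy(DisplacementField(grid, u), params)
        domain_volume = 16**3 * 1.0
        expected = (params.lame_mu + params.lame_lambda / 2.0) * alpha**2 * domain_volume
        assert got == pytest.approx(expected, rel=1e-12)

    def test_energy_scales_quadratically(self, unit_grid):
        rng = np.random.default_rng(2)
        params = RegistrationParams()
        u = 0.5 * rng.normal(size=(8, 8, 8, 3))
        e1 = elastic_energy(DisplacementField(unit_grid, u), params)
        e3 = elastic_energy(DisplacementField(unit_grid, 3.0 * u), params)
        assert e3 == pytest.approx(9.0 * e1, rel=1e-12)
        assert e1 >= 0.0


class TestElasticOperator:
    def test_zero_and_constant_fields_map_to_zero(self, aniso_grid):
        params = RegistrationParams()
        zero = elastic_operator_apply(DisplacementField.zero(aniso_grid), params)
        assert np.all(zero.vectors == 0.0)
        const = np.ones(aniso_grid.shape + (3,)) * [2.0, 1.0, -1.0]
        out = elastic_operator_apply(DisplacementField(aniso_grid, const), params)
        assert np.allclose(out.vectors, 0.0, atol=1e-14)

    @pytest.mark.parametrize(
        "shape,spacing",
        [((4, 4, 4), (1.0, 1.0, 1.0)), ((5, 4, 3), (2.0, 1.5, 3.0)), ((6, 6, 6), (1.0, 2.0, 0.5))],
    )
    def test_matches_dense_stencil_matrix(self, shape, spacing):
        grid = VolumeGrid(shape, spacing)
        params = RegistrationParams(lame_mu=1.0, lame_lambda=0.25)
        A = dense_navier_lame_matrix(grid, params)
        rng = np.random.default_rng(42)
        for _ in range(10):
            u = rng.normal(size=grid.shape + (3,))
            got = elastic_operator_apply(DisplacementField(grid, u), params).vectors
            expected = (A @ u.ravel()).reshape(grid.shape + (3,))
            assert np.max(np.abs(got - expected)) < 1e-10

    def test_operator_is_linear(self, unit_grid):
        rng = np.random.default_rng(3)
        params = RegistrationParams()
        u = rng.normal(size=(8, 8, 8, 3))
        v = rng.normal(size=(8, 8, 8, 3))
        lhs = elastic_operator_apply(
            DisplacementField(unit_grid, 2.0 * u - 0.5 * v), params
        ).vectors
        rhs = 2.0 * elastic_operator_apply(
            DisplacementField(unit_grid, u), params
        ).vectors - 0.5 * elastic_operator_apply(
            DisplacementField(unit_grid, v), params
        ).vectors
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestForceVector:
    def test_aligned_images_give_zero_force(self, unit_grid):
        rng = np.random.default_rng(4)
        vol = ScalarVolume(unit_grid, rng.normal(size=(8, 8, 8)))
        f = force_vector(vol, vol, DisplacementField.zero(unit_grid))
        assert np.allclose(f.vectors, 0.0)

    def test_constant_template_gives_zero_force(self, unit_grid):
        tpl = ScalarVolume(unit_grid, np.full((8, 8, 8), 30.0))
        ref = ScalarVolume(unit_grid, np.random.default_rng(5).normal(size=(8, 8, 8)))
        f = force_vector(ref, tpl, DisplacementField.zero(unit_grid))
        assert np.allclose(f.vectors, 0.0)

    def test_ramp_template_analytic_force(self):
        # T = x, R = x + c: residual -c, grad T = (1,0,0) => f = +c along x
        grid = VolumeGrid((10, 4, 4), (1.0, 1.0, 1.0))
        x = np.broadcast_to(
            np.arange(10, dtype=float)[:, None, None], (10, 4, 4)
        ).copy()
        c = 2.5
        f = force_vector(
            ScalarVolume(grid, x + c),
            ScalarVolume(grid, x),
            DisplacementField.zero(grid),
        )
        assert np.allclose(f.vectors[..., 0], c)
        assert np.allclose(f.vectors[..., 1:], 0.0)


class TestLinearSolve:
    def test_zero_force_zero_state_gives_zero_update(self, unit_grid):
        params = RegistrationParams()
        zero = DisplacementField.zero(unit_grid)
        du = solve_displacement_update(zero, zero, params)
        assert np.all(du.vectors == 0.0)

    def test_recovers_known_zero_mean_solution(self, unit_grid):
        # build rhs = (w*A) applied to a known smooth zero-mean field
        params = RegistrationParams(cg_tol=1e-10, max_cg_iters=2000)
        rng = np.random.default_rng(6)
        from scipy import ndimage

        w_field = ndimage.gaussian_filter(rng.normal(size=(8, 8, 8, 3)), (2, 2, 2, 0))
        w_field -= w_field.mean(axis=(0, 1, 2), keepdims=True)
        eps = _tikhonov_eps(unit_grid, params)
        rhs = params.reg_weight * _stabilized_operator(w_field, unit_grid, params, eps)
        du = solve_displacement_update(
            DisplacementField.unchecked(unit_grid, rhs),
            DisplacementField.zero(unit_grid),
            params,
        )
        scale = np.abs(w_field).max()
        assert np.max(np.abs(du.vectors - w_field)) < 1e-4 * scale

    def test_system_operator_is_symmetric(self, aniso_grid):
        params = RegistrationParams()
        eps = _tikhonov_eps(aniso_grid, params)
        rng = np.random.default_rng(7)
        for _ in range(5):
            v = rng.normal(size=aniso_grid.shape + (3,))
            w = rng.normal(size=aniso_grid.shape + (3,))
            Av = _stabilized_operator(v, aniso_grid, params, eps)
            Aw = _stabilized_operator(w, aniso_grid, params, eps)
            lhs = float(np.sum(Av * w))
            rhs = float(np.sum(v * Aw))
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-10)


class TestRegisterPair:
    def test_identical_images_converge_to_zero_field(self, small_phantom):
        series, truth = small_phantom
        frame = series.frames[truth.reference_index]
        result = register_pair(frame, frame)
        assert result.converged
        assert result.displacement.max_magnitude_mm() < 0.05
        assert result.final_ssd == pytest.approx(0.0)

    def test_constant_images_warn_and_return_zero(self, unit_grid):
        vol = ScalarVolume(unit_grid, np.full((8, 8, 8), 7.0))
        with pytest.warns(UserWarning, match="zero intensity variance"):
            result = register_pair(vol, vol)
        assert np.all(result.displacement.vectors == 0.0)

    def test_translated_blob_recovered(self):
        # Gaussian blob translated by 2 voxels along x
        grid = VolumeGrid((32, 32, 16), (2.0, 2.0, 2.0))
        x, y, z = np.meshgrid(*(np.arange(n) * 2.0 for n in (32, 32, 16)), indexing="ij")
        blob = lambda cx: 200.0 * np.exp(
            -(((x - cx) ** 2 + (y - 32) ** 2 + (z - 16) ** 2) / (2 * 8.0**2))
        )
        ref = ScalarVolume(grid, blob(28.0))
        tpl = ScalarVolume(grid, blob(32.0))  # blob 2 voxels (4 mm) to the right
        result = register_pair(ref, tpl, RegistrationParams())
        support = blob(30.0) > 20.0
        mean_ux = result.displacement.vectors[..., 0][support].mean()
        assert abs(mean_ux - 4.0) < 2.0  # within half a voxel... 1 voxel = 2 mm
        assert abs(result.displacement.vectors[..., 1][support].mean()) < 1.0

    def test_registration_is_deterministic(self, small_phantom):
        series, truth = small_phantom
        r1 = register_pair(series.frames[6], series.frames[7])
        r2 = register_pair(series.frames[6], series.frames[7])
        assert np.array_equal(r1.displacement.vectors, r2.displacement.vectors)
        assert r1.final_ssd == r2.final_ssd

    def test_stronger_regularization_reduces_elastic_energy(self, small_phantom):
        series, truth = small_phantom
        params = RegistrationParams()
        energies = []
        for w in (1e3, 1e4, 1e5):
            p = RegistrationParams(reg_weight=w)
            res = register_pair(series.frames[6], series.frames[7], p)
            energies.append(elastic_energy(res.displacement, params))
        assert energies[0] >= energies[1] >= energies[2]


class TestLameConversion:
    def test_round_trip_against_standard_relations(self):
        mu, lam = lame_from_elastic_moduli(young=2.02, poisson=0.01)
        assert mu == pytest.approx(1.0)
        # E = mu*(3*lam + 2*mu)/(lam + mu)
        E = mu * (3 * lam + 2 * mu) / (lam + mu)
        assert E == pytest.approx(2.02)
        with pytest.raises(ValueError):
            lame_from_elastic_moduli(1.0, 0.6)
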