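"""Pairwise variational elastic registration of two CT time frames.

The method minimises a joint functional

    J[u] = SSD(R, T; u) + alpha * S_elastic[u]

where ``SSD`` is the sum-of-squared-differences similarity between the
reference frame ``R`` and the template frame ``T`` warped by the
displacement ``u``, and ``S_elastic`` is the linear-elastic potential with
Lame parameters (mu, lambda).  The Euler-Lagrange condition couples the
Navier-Lame operator ``mu * Lap(u) + (mu + lambda) * grad(div u)`` with an
intensity-driven force term; it is discretised with finite differences and
Neumann (zero normal derivative) boundary conditions and solved by an outer
fixed-point iteration whose linear elastic system is handled by conjugate
gradients, all embedded in a coarse-to-fine multi-resolution pyramid.

Displacements are kept in physical mm throughout, so the convergence rule
(maximum voxelwise update below 0.05 mm) applies directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DisplacementField, ScalarVolume, VolumeGrid, _check_same_grid

__all__ = [
    "RegistrationParams",
    "RegistrationResult",
    "RegistrationError",
    "ssd_similarity",
    "elastic_energy",
    "elastic_operator_apply",
    "force_vector",
    "solve_displacement_update",
    "register_pair",
]


class RegistrationError(RuntimeError):
    """Raised when the linear solver diverges or inputs are unusable."""


def lame_from_elastic_moduli(young: float, poisson: float) -> tuple[float, float]:
    """Convert Young's modulus E and Poisson ratio nu to Lame (mu, lambda)."""
    if not 0 <= poisson < 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    mu = young / (2.0 * (1.0 + poisson))
    lam = young * poisson / ((1.0 + poisson) * (1.0 - 2.0 * poisson))
    return mu, lam


# Default Lame parameters: mu normalised to 1 with a small Poisson ratio
# (near-compressible tissue model, stiff enough to resist contrast-inflow
# forces); lambda follows from the (E, nu) relations.
_DEFAULT_MU, _DEFAULT_LAMBDA = 1.0, lame_from_elastic_moduli(2.02, 0.01)[1]


@dataclass
class RegistrationParams:
    """Controls for the elastic registration solver.

    ``reg_weight`` balances the elastic regulariser against the SSD force;
    its default was calibrated on the synthetic phantom (the smallest weight
    at which identical-image registration stays below the convergence
    tolerance while known smooth warps are still recovered) because
    absolute literature values do not transfer across intensity scales.
    """

    lame_mu: float = _DEFAULT_MU
    lame_lambda: float = _DEFAULT_LAMBDA
    reg_weight: float = 3000.0
    convergence_tol_mm: float = 0.05
    max_outer_iters: int = 50
    max_cg_iters: int = 200
    cg_tol: float = 1e-6
    pyramid_levels: int = 3
    skip_finest_level: bool = True

    def __post_init__(self) -> None:
        if self.lame_mu <= 0:
            raise ValueError("lame_mu must be > 0 (elliptic elastic operator)")
        if self.lame_lambda < 0:
            raise ValueError("lame_lambda must be >= 0")
        if self.reg_weight <= 0:
            raise ValueError("reg_weight must be > 0")
        if self.convergence_tol_mm <= 0:
            raise ValueError("convergence_tol_mm must be > 0")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


@dataclass
class RegistrationResult:
    displacement: DisplacementField
    final_ssd: float
    final_energy: float
    outer_iterations: int
    converged: bool
    per_level_log: list[tuple[int, int, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# warping and finite-difference helpers
# ---------------------------------------------------------------------------


def warp_values(values: np.ndarray, grid: VolumeGrid, vectors: np.ndarray) -> np.ndarray:
    """Trilinearly sample ``values`` at x + u(x); edge values clamp outside."""
    idx = np.indices(grid.shape, dtype=float)
    for ax in range(3):
        idx[ax] += vectors[..., ax] / grid.spacing[ax]
    return ndimage.map_coordinates(values, idx, order=1, mode="nearest")


def _gradient_mm(values: np.ndarray, grid: VolumeGrid) -> list[np.ndarray]:
    """Central-difference spatial gradient in HU/mm (one-sided at faces)."""
    return list(np.gradient(values, *grid.spacing))


def _second_diff(a: np.ndarray, axis: int, h: float) -> np.ndarray:
    """(a[i+1] - 2 a[i] + a[i-1]) / h^2 with Neumann (edge-replicated) ghosts."""
    pad = [(0, 0)] * a.ndim
    pad[axis] = (1, 1)
    ap = np.pad(a, pad, mode="edge")
    sl_p = [slice(None)] * a.ndim
    sl_m = [slice(None)] * a.ndim
    sl_c = [slice(None)] * a.ndim
    sl_p[axis] = slice(2, None)
    sl_m[axis] = slice(0, -2)
    sl_c[axis] = slice(1, -1)
    return (ap[tuple(sl_p)] - 2.0 * ap[tuple(sl_c)] + ap[tuple(sl_m)]) / h**2


def _cross_diff(a: np.ndarray, ax1: int, ax2: int, h1: float, h2: float) -> np.ndarray:
    """Mixed second derivative d2/dx1 dx2 with Neumann ghosts on both axes."""
    pad = [(0, 0)] * a.ndim
    pad[ax1] = (1, 1)
    pad[ax2] = (1, 1)
    ap = np.pad(a, pad, mode="edge")

    def sl(o1: int, o2: int) -> tuple[slice, ...]:
        s = [slice(None)] * a.ndim
        s[ax1] = slice(1 + o1, ap.shape[ax1] - 1 + o1)
        s[ax2] = slice(1 + o2, ap.shape[ax2] - 1 + o2)
        return tuple(s)

    return (ap[sl(1, 1)] - ap[sl(1, -1)] - ap[sl(-1, 1)] + ap[sl(-1, -1)]) / (
        4.0 * h1 * h2
    )


# ---------------------------------------------------------------------------
# functional terms
# ---------------------------------------------------------------------------


def ssd_similarity(
    reference: ScalarVolume,
    template: ScalarVolume,
    displacement: DisplacementField,
) -> float:
    """Sum-of-squared-differences similarity 1/2 * integral (T(x+u) - R(x))^2."""
    grid = _check_same_grid(reference.grid, template.grid, displacement.grid)
    warped = warp_values(template.values, grid, displacement.vectors)
    diff = warped - reference.values
    return 0.5 * float(np.sum(diff * diff)) * grid.voxel_volume_mm3


def elastic_energy(displacement: DisplacementField, params: RegistrationParams) -> float:
    """Discretised linear-elastic potential of a displacement field.

    mu/4 * sum_jk (d_j u_k + d_k u_j)^2 + lambda/2 * (div u)^2, integrated
    over the grid.  Zero for any rigid translation.
    """
    grid = displacement.grid
    u = displacement.vectors
    grads = [_gradient_mm(u[..., k], grid) for k in range(3)]  # grads[k][j] = d_j u_k
    sym = 0.0
    div = np.zeros(grid.shape)
    for k in range(3):
        div += grads[k][k]
        for j in range(3):
            sym_jk = grads[k][j] + grads[j][k]
            sym += np.sum(sym_jk * sym_jk)
    mu, lam = params.lame_mu, params.lame_lambda
    total = mu / 4.0 * sym + lam / 2.0 * float(np.sum(div * div))
    return float(total) * grid.voxel_volume_mm3


def _navier_lame(u: np.ndarray, grid: VolumeGrid, params: RegistrationParams) -> np.ndarray:
    h = grid.spacing
    mu, lam = params.lame_mu, params.lame_lambda
    out = np.zeros_like(u)
    for k in range(3):
        lap = sum(_second_diff(u[..., k], j, h[j]) for j in range(3))
        # d_k(div u) = sum_m d_k d_m u_m
        grad_div = _second_diff(u[..., k], k, h[k])
        for m in range(3):
            if m != k:
                grad_div = grad_div + _cross_diff(u[..., m], k, m, h[k], h[m])
        out[..., k] = mu * lap + (mu + lam) * grad_div
    return out


def elastic_operator_apply(
    displacement: DisplacementField, params: RegistrationParams
) -> DisplacementField:
    """Navier-Lame operator mu*Lap(u) + (mu+lambda)*grad(div u).

    Second-order central differences with Neumann ghost values at the faces;
    linear in u, and identically zero for any constant field.
    """
    return DisplacementField.unchecked(
        displacement.grid,
        _navier_lame(displacement.vectors, displacement.grid, params),
    )


def force_vector(
    reference: ScalarVolume,
    template: ScalarVolume,
    displacement: DisplacementField,
) -> DisplacementField:
    """SSD-driven force f(x) = -(T(x+u) - R(x)) * grad T(x+u), HU^2/mm."""
    grid = _check_same_grid(reference.grid, template.grid, displacement.grid)
    warped = warp_values(template.values, grid, displacement.vectors)
    residual = warped - reference.values
    grads = _gradient_mm(warped, grid)
    f = np.stack([-residual * g for g in grads], axis=-1)
    return DisplacementField.unchecked(grid, f)


# ---------------------------------------------------------------------------
# linear solve
# ---------------------------------------------------------------------------


def _tikhonov_eps(grid: VolumeGrid, params: RegistrationParams) -> float:
    """Small diagonal shift making the Neumann elastic system SPD.

    The pure Navier-Lame operator annihilates constant fields under Neumann
    conditions; a shift of 1e-6 times the stencil's diagonal scale restores
    definiteness without visibly changing solutions.
    """
    inv_h2 = [1.0 / s**2 for s in grid.spacing]
    diag_scale = 2.0 * params.lame_mu * sum(inv_h2) + 2.0 * (
        params.lame_mu + params.lame_lambda
    ) * max(inv_h2)
    return 1e-6 * diag_scale


def _central_zero(u: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Central first difference, zero on the two boundary slices (Neumann)."""
    out = np.zeros_like(u)
    sl_c = [slice(None)] * u.ndim
    sl_p = [slice(None)] * u.ndim
    sl_m = [slice(None)] * u.ndim
    sl_c[axis] = slice(1, -1)
    sl_p[axis] = slice(2, None)
    sl_m[axis] = slice(0, -2)
    out[tuple(sl_c)] = (u[tuple(sl_p)] - u[tuple(sl_m)]) / (2.0 * h)
    return out


def _central_zero_transpose(v: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Exact matrix transpose of :func:`_central_zero` (boundary slices ignored)."""
    w = v.copy()
    sl0 = [slice(None)] * v.ndim
    sl1 = [slice(None)] * v.ndim
    sl0[axis] = slice(0, 1)
    sl1[axis] = slice(-1, None)
    w[tuple(sl0)] = 0.0
    w[tuple(sl1)] = 0.0
    return -_shifted_central(w, axis, h)


def _shifted_central(w: np.ndarray, axis: int, h: float) -> np.ndarray:
    """(w[i+1] - w[i-1]) / 2h with zero ghosts outside the lattice."""
    out = np.zeros_like(w)
    sl_dst_lo = [slice(None)] * w.ndim
    sl_src_lo = [slice(None)] * w.ndim
    sl_dst_lo[axis] = slice(0, -1)
    sl_src_lo[axis] = slice(1, None)
    out[tuple(sl_dst_lo)] += w[tuple(sl_src_lo)]
    sl_dst_hi = [slice(None)] * w.ndim
    sl_src_hi = [slice(None)] * w.ndim
    sl_dst_hi[axis] = slice(1, None)
    sl_src_hi[axis] = slice(0, -1)
    out[tuple(sl_dst_hi)] -= w[tuple(sl_src_hi)]
    return out / (2.0 * h)


def _stabilized_operator(
    vectors: np.ndarray, grid: VolumeGrid, params: RegistrationParams, eps: float
) -> np.ndarray:
    """A u = K u + eps*u, with K the Galerkin assembly of the negated
    Navier-Lame operator.

    K = mu * sum_j D_j^T D_j (per component) + (mu+lambda) * C^T C with C the
    central-difference divergence; it is symmetric positive semidefinite by
    construction (the quadratic form is the discrete elastic energy in its
    grad/div split) and agrees with -(mu*Lap + (mu+lambda)*grad div) to
    second order in the interior; the eps shift removes the constant-field
    null space.
    """
    h = grid.spacing
    mu, lam = params.lame_mu, params.lame_lambda
    out = np.empty_like(vectors)
    div_c = sum(_central_zero(vectors[..., m], m, h[m]) for m in range(3))
    for k in range(3):
        lap = sum(_second_diff(vectors[..., k], j, h[j]) for j in range(3))
        out[..., k] = (
            -mu * lap
            + (mu + lam) * _central_zero_transpose(div_c, k, h[k])
            + eps * vectors[..., k]
        )
    return out


def solve_displacement_update(
    force: DisplacementField,
    current: DisplacementField,
    params: RegistrationParams,
    _context: str = "",
) -> DisplacementField:
    """Solve (reg_weight * A) du = f - reg_weight * A u_current for the update.

    A is the negated, Tikhonov-stabilised elastic operator; the system is
    solved with plain conjugate gradients to relative residual ``cg_tol``.
    Raises :class:`RegistrationError` if the CG residual norm increases over
    10 consecutive iterations.
    """
    grid = _check_same_grid(force.grid, current.grid)
    eps = _tikhonov_eps(grid, params)
    w = params.reg_weight

    def matvec(v: np.ndarray) -> np.ndarray:
        return w * _stabilized_operator(v, grid, params, eps)

    def project(v: np.ndarray) -> np.ndarray:
        # Remove the constant (rigid-translation) mode: the Neumann elastic
        # operator is translation-neutral, so the net force component would
        # otherwise be amplified by 1/eps into an arbitrarily large spurious
        # shift.  The operator maps the zero-mean subspace to itself, so CG
        # stays well-conditioned on it.
        return v - v.mean(axis=(0, 1, 2), keepdims=True)

    b = project(force.vectors - matvec(current.vectors))
    x = np.zeros_like(b)
    r = b - matvec(x)
    p = r.copy()
    rs = float(np.sum(r * r))
    b_norm = float(np.sqrt(np.sum(b * b)))
    if b_norm == 0.0:
        return DisplacementField.unchecked(grid, x)
    tol2 = (params.cg_tol * b_norm) ** 2
    n_increase = 0
    prev_rs = rs
    for it in range(params.max_cg_iters):
        if rs <= tol2:
            break
        Ap = matvec(p)
        alpha = rs / float(np.sum(p * Ap))
        x = x + alpha * p
        r = project(r - alpha * Ap)
        rs_new = float(np.sum(r * r))
        n_increase = n_increase + 1 if rs_new > prev_rs else 0
        if n_increase >= 10 and rs_new > 4.0 * b_norm**2:
            raise RegistrationError(
                f"CG diverged ({_context or 'linear solve'}): residual increased "
                f"over 10 consecutive iterations, at iteration {it}"
            )
        prev_rs = rs_new
        p = r + (rs_new / rs) * p
        rs = rs_new
    return DisplacementField.unchecked(grid, x)


# ---------------------------------------------------------------------------
# multi-resolution pyramid
# ---------------------------------------------------------------------------


def _downsample_volume(vol: ScalarVolume) -> ScalarVolume:
    """Halve each axis (Gaussian pre-smoothing, sigma = 1 voxel, then stride 2).

    Axes shorter than 4 voxels are left at full resolution so the coarse
    grid never drops below the 2-voxel minimum.
    """
    strides = [2 if n >= 4 else 1 for n in vol.grid.shape]
    sigma = [1.0 if s == 2 else 0.0 for s in strides]
    smoothed = ndimage.gaussian_filter(vol.values, sigma=sigma, mode="nearest")
    sub = smoothed[:: strides[0], :: strides[1], :: strides[2]]
    grid = VolumeGrid(
        sub.shape,
        tuple(sp * st for sp, st in zip(vol.grid.spacing, strides)),
        vol.grid.origin,
    )
    return ScalarVolume(grid, sub)


def _resample_field(field: DisplacementField, target: VolumeGrid) -> DisplacementField:
    """Trilinearly resample a displacement field onto another grid (values in mm)."""
    if field.grid == target:
        return field.copy()
    centers = np.stack(np.broadcast_arrays(*target.voxel_centers()), axis=-1)
    idx = field.grid.world_to_index(centers.reshape(-1, 3)).T
    out = np.empty(target.shape + (3,))
    for k in range(3):
        out[..., k] = ndimage.map_coordinates(
            field.vectors[..., k], idx, order=1, mode="nearest"
        ).reshape(target.shape)
    return DisplacementField(target, out)


def _joint_energy(
    reference: ScalarVolume,
    template: ScalarVolume,
    u: DisplacementField,
    params: RegistrationParams,
) -> tuple[float, float]:
    ssd = ssd_similarity(reference, template, u)
    return ssd + params.reg_weight * elastic_energy(u, params), ssd


def _translation_step(
    reference: ScalarVolume,
    template: ScalarVolume,
    u: DisplacementField,
) -> np.ndarray:
    """Gauss-Newton step for the global rigid-translation mode.

    The elastic potential is translation-invariant, so this mode carries no
    regularizer curvature; its natural Newton step comes from the SSD alone:
    solve (sum g g^T) c = sum (R - T(x+u)) g with g = grad T(x+u).
    """
    grid = reference.grid
    warped = warp_values(template.values, grid, u.vectors)
    residual = warped - reference.values
    g = np.stack(_gradient_mm(warped, grid), axis=-1).reshape(-1, 3)
    H = g.T @ g
    H += 1e-6 * np.trace(H) / 3.0 * np.eye(3)
    b = -(g * residual.reshape(-1, 1)).sum(axis=0)
    try:
        c = np.linalg.solve(H, b)
    except np.linalg.LinAlgError:
        return np.zeros(3)
    # Trust region per outer iteration: an unbounded rigid step can push the
    # image out of overlap, where edge clamping makes the SSD spuriously
    # small.  The cap is physical (mm) so degenerate coarse pyramid levels
    # cannot take multi-voxel jumps.
    cap = 5.0
    norm = float(np.linalg.norm(c))
    return c if norm <= cap else c * (cap / norm)


def _optimize_level(
    reference: ScalarVolume,
    template: ScalarVolume,
    u: DisplacementField,
    params: RegistrationParams,
    level: int,
) -> tuple[DisplacementField, int, float, bool]:
    """Outer fixed-point iteration at one pyramid level."""
    energy, _ = _joint_energy(reference, template, u, params)
    max_update = np.inf
    converged = False
    it = 0
    for it in range(1, params.max_outer_iters + 1):
        force = force_vector(reference, template, u)
        du = solve_displacement_update(force, u, params, _context=f"level {level}")
        du.vectors += _translation_step(reference, template, u)
        # Step halving: accept the largest fraction of du not increasing J.
        step = 1.0
        accepted = False
        for _ in range(9):
            cand = DisplacementField.unchecked(u.grid, u.vectors + step * du.vectors)
            cand_energy, _ = _joint_energy(reference, template, cand, params)
            if cand_energy <= energy + 1e-12 * max(1.0, abs(energy)):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        max_update = step * du.max_magnitude_mm()
        u = cand
        energy = cand_energy
        if max_update < params.convergence_tol_mm:
            converged = True
            break
    return u, it, float(max_update), converged


def register_pair(
    reference: ScalarVolume,
    template: ScalarVolume,
    params: RegistrationParams | None = None,
    initial: DisplacementField | None = None,
) -> RegistrationResult:
    """Estimate the displacement warping ``template`` onto ``reference``.

    Coarse-to-fine multi-resolution: each level runs the fixed-point /
    conjugate-gradient iteration until the maximum voxelwise update falls
    below ``convergence_tol_mm``; when ``skip_finest_level`` is set (the
    default, mirroring a fast clinical workflow) the full-resolution level
    receives the upsampled coarse solution without further optimisation.
    """
    params = params or RegistrationParams()
    grid = _check_same_grid(reference.grid, template.grid)

    if np.ptp(reference.values) == 0.0 or np.ptp(template.values) == 0.0:
        warnings.warn(
            "registration input has zero intensity variance; returning zero field",
            stacklevel=2,
        )
        zero = DisplacementField.zero(grid)
        ssd = ssd_similarity(reference, template, zero)
        return RegistrationResult(zero, ssd, ssd, 0, True, [])

    # Build the pyramid: index 0 = finest.
    pyramid = [(reference, template)]
    for _ in range(params.pyramid_levels - 1):
        r, t = pyramid[-1]
        pyramid.append((_downsample_volume(r), _downsample_volume(t)))

    start_level = 1 if params.skip_finest_level and params.pyramid_levels > 1 else 0
    coarsest = params.pyramid_levels - 1
    u = (
        _resample_field(initial, pyramid[coarsest][0].grid)
        if initial is not None
        else DisplacementField.zero(pyramid[coarsest][0].grid)
    )

    total_iters = 0
    converged = False
    log: list[tuple[int, int, float]] = []
    for level in range(coarsest, start_level - 1, -1):
        ref_l, tpl_l = pyramid[level]
        u = _resample_field(u, ref_l.grid)
        u, iters, max_update, converged = _optimize_level(
            ref_l, tpl_l, u, params, level
        )
        total_iters += iters
        log.append((level, iters, max_update))

    u = _resample_field(u, grid)
    final_energy, final_ssd = _joint_energy(reference, template, u, params)
    return RegistrationResult(u, final_ssd, final_energy, total_iters, converged, log)
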