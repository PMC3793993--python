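"""Series-level motion compensation.

Stage two of the two-stage approach: pairwise displacement fields between
temporally adjacent frames are concatenated along the chain towards a
designated reference frame, and every frame is warped into that reference
geometry.  Fields always map a frame's coordinates towards the reference,
so ``warp_volume(frame_i, to_reference[i])`` produces the aligned frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    DisplacementField,
    PerfusionSeries,
    ScalarVolume,
    VolumeGrid,
    _check_same_grid,
)
from .registration import (
    RegistrationParams,
    RegistrationResult,
    register_pair,
    warp_values,
)

__all__ = [
    "MotionModel",
    "compose_fields",
    "build_motion_model",
    "warp_volume",
    "invert_field",
    "motion_compensate_series",
]


@dataclass
class MotionModel:
    """Pairwise adjacent-frame fields plus per-frame fields to the reference.

    ``pair_fields[i]`` maps the frame of pair (i, i+1) that lies farther
    from the reference into its nearer neighbour's geometry;
    ``to_reference[i]`` maps frame i all the way into the reference frame
    (identically zero at the reference itself).
    """

    reference_index: int
    pair_fields: list[DisplacementField]
    to_reference: list[DisplacementField]

    def __post_init__(self) -> None:
        n = len(self.to_reference)
        if not 0 <= self.reference_index < n:
            raise ValueError("reference_index out of range")
        if len(self.pair_fields) != max(n - 1, 0):
            raise ValueError("need exactly one pair field per adjacent frame pair")
        if self.to_reference[self.reference_index].max_magnitude_mm() != 0.0:
            raise ValueError("to_reference at the reference frame must be zero")


def _sample_field(field: DisplacementField, positions_mm: np.ndarray) -> np.ndarray:
    """Trilinear sample of each vector component at world positions (edge clamp)."""
    idx = field.grid.world_to_index(positions_mm.reshape(-1, 3)).T
    out = np.empty(positions_mm.shape)
    for k in range(3):
        out[..., k] = ndimage.map_coordinates(
            field.vectors[..., k], idx, order=1, mode="nearest"
        ).reshape(positions_mm.shape[:-1])
    return out


def compose_fields(
    outer: DisplacementField, inner: DisplacementField
) -> DisplacementField:
    """Concatenate two displacement fields: u(x) = inner(x) + outer(x + inner(x)).

    Warping by the composed field equals warping by ``inner`` and then by
    ``outer`` (up to interpolation); composing with a zero field on either
    side returns the other field unchanged.
    """
    grid = _check_same_grid(outer.grid, inner.grid)
    centers = np.stack(np.broadcast_arrays(*grid.voxel_centers()), axis=-1)
    displaced = centers + inner.vectors
    return DisplacementField(grid, inner.vectors + _sample_field(outer, displaced))


def invert_field(
    field: DisplacementField, n_iters: int = 30, tol_mm: float = 1e-3
) -> DisplacementField:
    """Numerically invert a displacement field by fixed-point iteration.

    Finds v with v(x) + u(x + v(x)) ~ 0, i.e. the field undoing ``u``.
    Accurate for smooth, moderate-amplitude fields (exact for translations).
    """
    grid = field.grid
    centers = np.stack(np.broadcast_arrays(*grid.voxel_centers()), axis=-1)
    v = -field.vectors.copy()
    for _ in range(n_iters):
        v_new = -_sample_field(field, centers + v)
        if float(np.max(np.abs(v_new - v))) < tol_mm:
            v = v_new
            break
        v = v_new
    return DisplacementField(grid, v)


def build_motion_model(
    pair_fields: list[DisplacementField],
    reference_index: int,
    grid: "VolumeGrid | None" = None,
) -> MotionModel:
    """Chain adjacent-pair fields into per-frame to-reference fields.

    For frames past the reference the chain composes rightward pair fields
    (each mapping frame i+1 into frame i); before the reference it composes
    leftward ones (frame i into frame i+1).  The reference entry is zero.
    A single-frame series (empty pair list) needs an explicit ``grid``.
    """
    n_frames = len(pair_fields) + 1
    if not 0 <= reference_index < n_frames:
        raise ValueError(
            f"reference_index {reference_index} out of range for {n_frames} frames"
        )
    if any(f is None for f in pair_fields):
        raise ValueError("missing pair field in the chain")
    if pair_fields:
        grid = _check_same_grid(*(f.grid for f in pair_fields))
    elif grid is None:
        raise ValueError("grid required for a single-frame (empty-chain) model")
    to_ref: list[DisplacementField] = [None] * n_frames  # type: ignore[list-item]
    to_ref[reference_index] = DisplacementField.zero(grid)
    for i in range(reference_index + 1, n_frames):
        # pair_fields[i-1] maps frame i into frame i-1 geometry
        to_ref[i] = compose_fields(outer=pair_fields[i - 1], inner=to_ref[i - 1])
    for i in range(reference_index - 1, -1, -1):
        # pair_fields[i] maps frame i into frame i+1 geometry
        to_ref[i] = compose_fields(outer=pair_fields[i], inner=to_ref[i + 1])
    return MotionModel(reference_index, list(pair_fields), to_ref)


def warp_volume(volume: ScalarVolume, displacement: DisplacementField) -> ScalarVolume:
    """Deform a volume: output(x) = volume(x + u(x)), trilinear with edge clamp.

    A zero field returns the input bit-identically; trilinear sampling keeps
    every output value inside the input's [min, max] range.
    """
    grid = _check_same_grid(volume.grid, displacement.grid)
    if not displacement.vectors.any():
        return volume.copy()
    return ScalarVolume(grid, warp_values(volume.values, grid, displacement.vectors))


def motion_compensate_series(
    series: PerfusionSeries,
    params: RegistrationParams | None = None,
    reference_index: int | None = None,
) -> tuple[PerfusionSeries, MotionModel]:
    """Align every frame of a dynamic series into one reference frame.

    Adjacent pairs are registered with the frame farther from the reference
    as the template (so each estimated field maps it towards the
    reference); the fields are concatenated into per-frame to-reference
    fields and all frames are warped.  The reference frame itself is
    returned unmodified; grid and acquisition times never change.
    """
    params = params or RegistrationParams()
    n = series.n_frames
    if reference_index is None:
        reference_index = n // 2  # middle frame: shortest composition chains
    if not 0 <= reference_index < n:
        raise ValueError(f"reference_index {reference_index} out of range")
    if n == 1:
        model = MotionModel(0, [], [DisplacementField.zero(series.grid)])
        return PerfusionSeries([series.frames[0].copy()], series.times_s), model

    pair_fields: list[DisplacementField] = []
    for i in range(n - 1):
        if i < reference_index:
            ref_frame, tpl_frame = series.frames[i + 1], series.frames[i]
        else:
            ref_frame, tpl_frame = series.frames[i], series.frames[i + 1]
        if np.ptp(tpl_frame.values) == 0.0:
            warnings.warn(
                f"frame pair ({i}, {i + 1}): degenerate constant frame, "
                "using identity field",
                stacklevel=2,
            )
            pair_fields.append(DisplacementField.zero(series.grid))
            continue
        try:
            result: RegistrationResult = register_pair(ref_frame, tpl_frame, params)
        except Exception as exc:  # noqa: BLE001 - annotate pair then re-raise
            raise RuntimeError(
                f"registration failed on frame pair ({i}, {i + 1}): {exc}"
            ) from exc
        pair_fields.append(result.displacement)

    model = build_motion_model(pair_fields, reference_index)
    frames = [
        series.frames[i].copy()
        if i == reference_index
        else warp_volume(series.frames[i], model.to_reference[i])
        for i in range(n)
    ]
    return PerfusionSeries(frames, series.times_s.copy()), model
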