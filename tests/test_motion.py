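"""Field composition, motion model chaining and volume warping."""

import numpy as np
import pytest
from scipy import ndimage

from cardiomoco import (
    DisplacementField,
    MotionModel,
    PerfusionSeries,
    ScalarVolume,
    VolumeGrid,
    build_motion_model,
    compose_fields,
    invert_field,
    motion_compensate_series,
    warp_volume,
)


def _translation(grid, vec):
    u = np.zeros(grid.shape + (3,))
    u[..., :] = vec
    return DisplacementField(grid, u)


def _smooth_field(grid, seed=0, scale=1.5):
    rng = np.random.default_rng(seed)
    u = ndimage.gaussian_filter(rng.normal(size=grid.shape + (3,)), (3, 3, 3, 0))
    u *= scale / np.abs(u).max()
    return DisplacementField(grid, u)


class TestComposeFields:
    def test_zero_is_identity_element(self, unit_grid):
        f = _smooth_field(unit_grid, seed=1)
        zero = DisplacementField.zero(unit_grid)
        assert np.allclose(compose_fields(zero, f).vectors, f.vectors)
        assert np.allclose(compose_fields(f, zero).vectors, f.vectors)

    def test_translations_compose_additively(self, unit_grid):
        a = _translation(unit_grid, (1.0, -0.5, 0.25))
        b = _translation(unit_grid, (0.5, 0.5, 0.0))
        comp = compose_fields(a, b)
        assert np.allclose(comp.vectors, np.asarray([1.5, 0.0, 0.25]))

    def test_field_composed_with_numeric_inverse_is_near_zero(self):
        grid = VolumeGrid((16, 16, 16))
        f = _smooth_field(grid, seed=2, scale=1.2)
        finv = invert_field(f)
        comp = compose_fields(f, finv)
        interior = comp.vectors[3:-3, 3:-3, 3:-3]
        assert np.max(np.linalg.norm(interior, axis=-1)) < 0.1  # < 0.1 voxel

    def test_grid_mismatch_is_error(self, unit_grid, aniso_grid):
        with pytest.raises(ValueError, match="grid mismatch"):
            compose_fields(
                DisplacementField.zero(unit_grid), DisplacementField.zero(aniso_grid)
            )


class TestMotionModel:
    def test_reference_entry_is_zero_field(self, unit_grid):
        pair = [_translation(unit_grid, (1, 0, 0)) for _ in range(3)]
        model = build_motion_model(pair, reference_index=2)
        assert model.to_reference[2].max_magnitude_mm() == 0.0

    def test_three_frame_translation_chain(self, unit_grid):
        # reference 0; pair fields map frame i+1 into frame i geometry
        t1 = _translation(unit_grid, (1.0, 0.0, 0.0))
        t2 = _translation(unit_grid, (0.0, 2.0, 0.0))
        model = build_motion_model([t1, t2], reference_index=0)
        assert np.allclose(model.to_reference[0].vectors, 0.0)
        assert np.allclose(model.to_reference[1].vectors, np.asarray([1.0, 0.0, 0.0]))
        assert np.allclose(model.to_reference[2].vectors, np.asarray([1.0, 2.0, 0.0]))

    def test_reference_at_last_frame_reverses_chain(self, unit_grid):
        t1 = _translation(unit_grid, (1.0, 0.0, 0.0))
        t2 = _translation(unit_grid, (0.0, 2.0, 0.0))
        model = build_motion_model([t1, t2], reference_index=2)
        # now pair fields map frame i into frame i+1 geometry
        assert np.allclose(model.to_reference[0].vectors, np.asarray([1.0, 2.0, 0.0]))
        assert np.allclose(model.to_reference[1].vectors, np.asarray([0.0, 2.0, 0.0]))

    def test_empty_chain_needs_grid(self, unit_grid):
        with pytest.raises(ValueError):
            build_motion_model([], reference_index=0)
        model = build_motion_model([], reference_index=0, grid=unit_grid)
        assert len(model.to_reference) == 1

    def test_invariants_enforced(self, unit_grid):
        with pytest.raises(ValueError):
            MotionModel(
                reference_index=0,
                pair_fields=[],
                to_reference=[_translation(unit_grid, (1, 0, 0))],
            )


class TestWarpVolume:
    def test_zero_field_returns_identical_volume(self, unit_grid):
        rng = np.random.default_rng(0)
        vol = ScalarVolume(unit_grid, rng.normal(size=(8, 8, 8)))
        out = warp_volume(vol, DisplacementField.zero(unit_grid))
        assert np.array_equal(out.values, vol.values)

    def test_integer_voxel_translation_shifts_lattice(self):
        grid = VolumeGrid((10, 6, 6), (2.0, 1.0, 1.0))
        rng = np.random.default_rng(1)
        vol = ScalarVolume(grid, rng.normal(size=(10, 6, 6)))
        out = warp_volume(vol, _translation(grid, (2.0, 0.0, 0.0)))  # +1 voxel in x
        assert np.allclose(out.values[:-1], vol.values[1:], atol=1e-12)

    def test_warped_values_stay_within_input_range(self, unit_grid):
        rng = np.random.default_rng(2)
        vol = ScalarVolume(unit_grid, rng.normal(50, 30, size=(8, 8, 8)))
        out = warp_volume(vol, _smooth_field(unit_grid, seed=3))
        assert out.values.min() >= vol.values.min() - 1e-12
        assert out.values.max() <= vol.values.max() + 1e-12

    def test_warp_then_inverse_round_trip(self):
        grid = VolumeGrid((24, 24, 24))
        x, y, z = np.meshgrid(*(np.arange(24.0),) * 3, indexing="ij")
        smooth_img = np.sin(x / 4.0) * np.cos(y / 5.0) + 0.2 * z / 24.0
        vol = ScalarVolume(grid, 100.0 * smooth_img)
        f = _smooth_field(grid, seed=4, scale=1.5)
        out = warp_volume(warp_volume(vol, f), invert_field(f))
        interior = (slice(4, -4),) * 3
        dyn = np.ptp(vol.values)
        assert np.max(np.abs(out.values[interior] - vol.values[interior])) < 0.02 * dyn


class TestMotionCompensateSeries:
    def test_identical_frames_pass_through(self, unit_grid):
        rng = np.random.default_rng(5)
        base = rng.normal(100, 30, size=(8, 8, 8))
        series = PerfusionSeries(
            [ScalarVolume(unit_grid, base.copy()) for _ in range(4)],
            np.arange(4.0) * 2.0,
        )
        comp, model = motion_compensate_series(series)
        for i in range(4):
            assert model.to_reference[i].max_magnitude_mm() < 0.05
        assert np.allclose(comp.as_array(), series.as_array(), atol=1.0)

    def test_grid_times_and_frame_count_preserved(self, small_phantom_compensated):
        series, truth, comp, model = small_phantom_compensated
        assert comp.n_frames == series.n_frames
        assert comp.grid == series.grid
        assert np.array_equal(comp.times_s, series.times_s)
        # reference frame untouched
        ref = truth.reference_index
        assert np.array_equal(
            comp.frames[ref].values, series.frames[ref].values
        )

    def test_translation_motion_ssd_reduced_95_percent(self):
        # integer-voxel translations on a constant background: synthesis is
        # interpolation-exact, so compensation should remove essentially the
        # whole frame-to-reference SSD
        grid = VolumeGrid((32, 32, 12), (4.0, 4.0, 4.0))
        x, y, z = np.meshgrid(
            *(np.arange(n) * 4.0 for n in (32, 32, 12)), indexing="ij"
        )
        cx, cy, cz = 62.0, 62.0, 22.0
        rng = np.random.default_rng(8)
        texture = ndimage.gaussian_filter(rng.normal(size=grid.shape), 1.2)
        taper = 1.0 - 0.5 * ((z - cz) / 30.0) ** 2
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        ring = (r2 > (28 * taper) ** 2) & (r2 < (45 * taper) ** 2)
        base = np.where(ring, 150.0, 0.0) + 25.0 * texture * (
            r2 < (45 * taper) ** 2
        )
        shifts = [(0.0, 0.0, 0.0), (8.0, -4.0, 0.0), (-4.0, 8.0, 0.0)]
        frames = []
        for sh in shifts:
            u = np.zeros(grid.shape + (3,))
            u[..., :] = sh
            frames.append(warp_volume(ScalarVolume(grid, base), DisplacementField(grid, u)))
        series = PerfusionSeries(frames, np.arange(3.0) * 2.0)
        comp, model = motion_compensate_series(series, reference_index=0)
        ssd_before = sum(
            np.sum((series.frames[i].values - base) ** 2) for i in (1, 2)
        )
        ssd_after = sum(np.sum((comp.frames[i].values - base) ** 2) for i in (1, 2))
        assert ssd_after < 0.05 * ssd_before
        # recovered to-reference fields are the negated shifts
        for i in (1, 2):
            mean_rec = model.to_reference[i].vectors.reshape(-1, 3).mean(axis=0)
            assert np.allclose(mean_rec, -np.asarray(shifts[i]), atol=0.5)

    def test_degenerate_constant_frame_warns_uses_identity(self, unit_grid):
        rng = np.random.default_rng(9)
        frames = [
            ScalarVolume(unit_grid, rng.normal(100, 20, size=(8, 8, 8))),
            ScalarVolume(unit_grid, np.full((8, 8, 8), 55.0)),
        ]
        series = PerfusionSeries(frames, [0.0, 2.0])
        with pytest.warns(UserWarning, match="degenerate"):
            comp, model = motion_compensate_series(series, reference_index=0)
        assert model.to_reference[1].max_magnitude_mm() == 0.0
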