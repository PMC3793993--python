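"""Shared fixtures: small grids, volumes and phantom instances.

All data is generated programmatically; phantom fixtures use fixed seeds
so every run sees identical inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiomoco import (
    PerfusionSeries,
    PhantomConfig,
    ScalarVolume,
    VolumeGrid,
    generate_phantom,
)


@pytest.fixture
def unit_grid() -> VolumeGrid:
    return VolumeGrid((8, 8, 8), (1.0, 1.0, 1.0))


@pytest.fixture
def aniso_grid() -> VolumeGrid:
    return VolumeGrid((10, 8, 6), (2.0, 1.5, 3.0), (-5.0, 0.0, 2.5))


@pytest.fixture
def ramp_volume(unit_grid) -> ScalarVolume:
    x = np.arange(8, dtype=float)
    return ScalarVolume(unit_grid, np.broadcast_to(x[:, None, None], (8, 8, 8)).copy())


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse, fast default phantom with lesion, motion spikes and noise."""
    config = PhantomConfig(
        grid=VolumeGrid((48, 48, 10), (250.0 / 48, 250.0 / 48, 3.0)),
        seed=11,
    )
    return generate_phantom(config)


@pytest.fixture(scope="session")
def still_phantom():
    """Motion- and noise-free phantom: frames differ only by enhancement."""
    config = PhantomConfig(
        grid=VolumeGrid((32, 32, 8), (250.0 / 32, 250.0 / 32, 3.0)),
        motion_amplitude_mm=0.0,
        arrhythmia_frames=(),
        noise_sd_hu=0.0,
        texture_sd_hu=0.0,
        seed=7,
    )
    return generate_phantom(config)


@pytest.fixture
def constant_series(unit_grid) -> PerfusionSeries:
    frames = [ScalarVolume(unit_grid, np.full((8, 8, 8), 100.0)) for _ in range(5)]
    return PerfusionSeries(frames, np.arange(5) * 2.0)


@pytest.fixture(scope="session")
def small_phantom_compensated(small_phantom):
    """Motion-compensated version of the small phantom (computed once)."""
    import warnings

    from cardiomoco import motion_compensate_series

    series, truth = small_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp, model = motion_compensate_series(series)
    return series, truth, comp, model
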