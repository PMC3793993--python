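"""Synthetic dynamic cardiac phantom with complete ground truth.

The phantom is a 3D annular "myocardium" around a blood-pool core on a
constant background, with an optional hypoperfused sector lesion.  Each
tissue class follows an analytic gamma-variate contrast-enhancement curve
(the lesion with reduced amplitude and delayed onset); every frame is
deformed by a smooth sinusoidal displacement field, with extra translation
spikes on designated frames emulating extrasystoles during ECG-triggered
acquisition; stationary Gaussian noise in HU is added last.  Alongside the
series the generator emits the tissue labels, the per-frame ground-truth
displacement fields (frame towards reference geometry) and the true
enhancement parameters, so every downstream module can be validated
against known truth.

No attempt is made at anatomical realism: the geometry is chosen to be
simple enough for analytic ROIs yet rich enough to exercise registration
and edge-preserving filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import DisplacementField, PerfusionSeries, ROIMask, ScalarVolume, VolumeGrid
from .motion import invert_field, warp_volume

__all__ = [
    "GammaVariateParams",
    "PhantomConfig",
    "PhantomTruth",
    "gamma_variate",
    "generate_phantom",
]

LABEL_BACKGROUND = 0
LABEL_BLOOD_POOL = 1
LABEL_MYOCARDIUM = 2
LABEL_LESION = 3

LABEL_NAMES = {
    "background": LABEL_BACKGROUND,
    "blood_pool": LABEL_BLOOD_POOL,
    "myocardium": LABEL_MYOCARDIUM,
    "lesion": LABEL_LESION,
}


def gamma_variate(
    t_s: float | np.ndarray,
    baseline_hu: float,
    amplitude_hu: float,
    t0_s: float,
    alpha: float,
    beta_s: float,
) -> float | np.ndarray:
    """Peak-normalised gamma-variate bolus curve.

    baseline for t <= t0, then
    baseline + amplitude * ((t-t0)/(alpha*beta))**alpha * exp(alpha - (t-t0)/beta).
    The normalisation makes the peak value exactly baseline + amplitude,
    reached at t = t0 + alpha*beta, so ``amplitude_hu`` IS the true peak
    enhancement of the tissue class.
    """
    if alpha <= 0 or beta_s <= 0:
        raise ValueError("gamma-variate shape parameters alpha, beta must be > 0")
    t = np.asarray(t_s, dtype=float)
    dt = np.maximum(t - t0_s, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = baseline_hu + amplitude_hu * (dt / (alpha * beta_s)) ** alpha * np.exp(
            alpha - dt / beta_s
        )
    val = np.where(t <= t0_s, baseline_hu, val)
    return float(val) if np.isscalar(t_s) else val


@dataclass(frozen=True)
class GammaVariateParams:
    """Enhancement-curve parameters of one tissue class."""

    baseline_hu: float
    amplitude_hu: float
    t0_s: float
    alpha: float = 2.5
    beta_s: float = 2.4

    def at(self, t_s: float | np.ndarray) -> float | np.ndarray:
        return gamma_variate(
            t_s, self.baseline_hu, self.amplitude_hu, self.t0_s, self.alpha, self.beta_s
        )

    @property
    def peak_time_s(self) -> float:
        return self.t0_s + self.alpha * self.beta_s


def _default_enhancement() -> dict[str, GammaVariateParams]:
    # Blood pool follows a fast, high first-pass input curve; myocardial
    # tissue enhances later, less and far more gently (the tissue response
    # spreads the input bolus over many seconds); the lesion shows the
    # hallmark delayed (+4 s) and decreased enhancement.
    return {
        "background": GammaVariateParams(0.0, 0.0, 0.0),
        "blood_pool": GammaVariateParams(60.0, 300.0, 2.0, alpha=3.0, beta_s=1.5),
        "myocardium": GammaVariateParams(55.0, 80.0, 4.0, alpha=2.0, beta_s=5.0),
        "lesion": GammaVariateParams(55.0, 45.0, 8.0, alpha=2.0, beta_s=5.5),
    }


def _default_grid() -> VolumeGrid:
    # 250 mm in-plane field of view on a 64x64 matrix, 3 mm slices.
    return VolumeGrid((64, 64, 12), (250.0 / 64, 250.0 / 64, 3.0))


@dataclass
class PhantomConfig:
    """All knobs of the synthetic dynamic series; defaults emulate a
    15-acquisition alternate-cardiac-cycle stress perfusion scan at 60 bpm
    (one frame every ~2 s) with a sector lesion and two extrasystole-like
    motion spikes."""

    grid: VolumeGrid = field(default_factory=_default_grid)
    n_frames: int = 15
    frame_interval_s: float = 2.0
    blood_radius_mm: float = 22.0
    myocardium_outer_radius_mm: float = 42.0
    z_semi_axis_mm: float | None = None  # default: 1.1 * half the z extent
    lesion_sector_rad: tuple[float, float] | None = (0.0, np.pi / 2)
    lesion_depth_fraction: float = 0.7
    enhancement: dict[str, GammaVariateParams] = field(
        default_factory=_default_enhancement
    )
    motion_amplitude_mm: float = 3.0
    motion_wavelength_mm: float = 120.0
    motion_cycles: float = 1.5
    arrhythmia_frames: tuple[int, ...] = (3, 8)
    arrhythmia_shift_mm: float = 6.0
    texture_sd_hu: float = 12.0
    noise_sd_hu: float = 10.0
    reference_frame: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.noise_sd_hu < 0 or self.texture_sd_hu < 0:
            raise ValueError("noise and texture SDs must be >= 0")
        if self.blood_radius_mm >= self.myocardium_outer_radius_mm:
            raise ValueError("blood pool radius must be smaller than outer radius")
        if self.lesion_sector_rad is not None:
            lo, hi = self.lesion_sector_rad
            if not (0 <= lo < 2 * np.pi and 0 < hi <= 2 * np.pi and lo < hi):
                raise ValueError("lesion sector must lie within [0, 2*pi) with lo < hi")
            if not 0 < self.lesion_depth_fraction <= 1:
                raise ValueError("lesion depth fraction must be in (0, 1]")
        missing = set(LABEL_NAMES) - set(self.enhancement)
        if missing:
            raise ValueError(f"enhancement parameters missing for {sorted(missing)}")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_s

    @property
    def resolved_reference(self) -> int:
        return self.n_frames // 2 if self.reference_frame is None else self.reference_frame


@dataclass
class PhantomTruth:
    """Everything the generator knows: labels, true motion, true enhancement."""

    labels: ScalarVolume
    true_fields: list[DisplacementField]
    true_tdc_params: dict[str, GammaVariateParams]
    reference_index: int
    seed: int

    def label_mask(self, name: str, erode_voxels: int = 0) -> ROIMask:
        """ROI of one tissue class, optionally eroded away from class borders."""
        mask = self.labels.values == LABEL_NAMES[name]
        if erode_voxels > 0:
            mask = ndimage.binary_erosion(mask, iterations=erode_voxels)
        if not mask.any():
            raise ValueError(f"label '{name}' empty after eroding {erode_voxels}")
        return ROIMask(self.labels.grid, mask, name)


def _build_labels(config: PhantomConfig) -> np.ndarray:
    """Ellipsoid-tapered annular ventricle model.

    In-plane the shape is a blood-pool disc inside a myocardial annulus;
    both radii shrink towards the z ends (apex-like taper) so that
    through-plane motion is observable in the image data.
    """
    grid = config.grid
    x, y, z = grid.voxel_centers()
    cx, cy, cz = (
        o + (n - 1) * s / 2 for n, s, o in zip(grid.shape, grid.spacing, grid.origin)
    )
    z_semi = (
        config.z_semi_axis_mm
        if config.z_semi_axis_mm is not None
        else 1.1 * (grid.extent_mm[2] / 2.0 + grid.spacing[2] / 2.0)
    )
    taper2 = 1.0 - ((z - cz) / z_semi) ** 2
    taper = np.sqrt(np.maximum(taper2, 0.0))
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2) + np.zeros(grid.shape)
    taper = taper + np.zeros(grid.shape)
    labels = np.full(grid.shape, LABEL_BACKGROUND, dtype=int)
    labels[r <= taper * config.myocardium_outer_radius_mm] = LABEL_MYOCARDIUM
    labels[r <= taper * config.blood_radius_mm] = LABEL_BLOOD_POOL
    if config.lesion_sector_rad is not None:
        theta = np.mod(np.arctan2(y - cy, x - cx), 2 * np.pi) + np.zeros(grid.shape)
        lo, hi = config.lesion_sector_rad
        lesion_outer = config.blood_radius_mm + config.lesion_depth_fraction * (
            config.myocardium_outer_radius_mm - config.blood_radius_mm
        )
        lesion = (
            (labels == LABEL_MYOCARDIUM)
            & (theta >= lo)
            & (theta <= hi)
            & (r <= taper * lesion_outer)
        )
        if not lesion.any():
            raise ValueError("lesion sector lies outside the myocardium annulus")
        labels[lesion] = LABEL_LESION
    return labels


def _true_field(config: PhantomConfig, frame: int) -> DisplacementField:
    """Analytic ground-truth displacement of one frame towards the reference."""
    grid = config.grid
    ref = config.resolved_reference
    x, y, _ = grid.voxel_centers()
    cx, cy, _ = (o + (n - 1) * s / 2 for n, s, o in zip(grid.shape, grid.spacing, grid.origin))
    amp = config.motion_amplitude_mm * np.sin(
        2 * np.pi * config.motion_cycles * (frame - ref) / config.n_frames
    )
    k = 2 * np.pi / config.motion_wavelength_mm
    ux = amp * np.sin(k * (y - cy)) + np.zeros(grid.shape)
    uy = amp * np.sin(k * (x - cx) + np.pi / 3) + np.zeros(grid.shape)
    uz = 0.3 * amp * np.sin(k * ((x - cx) + (y - cy))) + np.zeros(grid.shape)
    vec = np.stack([ux, uy, uz], axis=-1)
    if frame in config.arrhythmia_frames and frame != ref:
        shift = config.arrhythmia_shift_mm / np.sqrt(2.0)
        vec[..., 0] += shift
        vec[..., 1] += shift
    return DisplacementField(grid, vec)


def generate_phantom(config: PhantomConfig) -> tuple[PerfusionSeries, PhantomTruth]:
    """Generate the dynamic series and its ground truth.

    Per frame: assign each tissue class its analytic enhancement value at
    the acquisition time, add a frozen smooth intra-tissue texture, deform
    by the (numerically inverted) ground-truth field, then add fresh
    Gaussian noise.  Identical seed and config reproduce the output
    bit-for-bit.
    """
    grid = config.grid
    labels = _build_labels(config)
    rng = np.random.default_rng(config.seed)

    # Frozen smooth texture riding with the tissue (zero in the background so
    # background SD measures pure noise).
    texture = ndimage.gaussian_filter(rng.normal(size=grid.shape), sigma=1.5)
    if texture.std() > 0:
        texture *= config.texture_sd_hu / texture.std()
    texture = texture * (labels != LABEL_BACKGROUND)

    name_by_label = {v: k for k, v in LABEL_NAMES.items()}
    times = config.times_s
    ref = config.resolved_reference
    if not 0 <= ref < config.n_frames:
        raise ValueError("reference_frame out of range")

    frames: list[ScalarVolume] = []
    true_fields: list[DisplacementField] = []
    for i, t in enumerate(times):
        class_values = np.zeros(max(LABEL_NAMES.values()) + 1)
        for lab, name in name_by_label.items():
            class_values[lab] = config.enhancement[name].at(float(t))
        ideal = ScalarVolume(grid, class_values[labels] + texture)
        tf = _true_field(config, i)
        true_fields.append(tf)
        if i == ref:
            moved = ideal
        else:
            moved = warp_volume(ideal, invert_field(tf))
        noisy = moved.values
        if config.noise_sd_hu > 0:
            noisy = noisy + rng.normal(scale=config.noise_sd_hu, size=grid.shape)
        frames.append(ScalarVolume(grid, noisy))

    series = PerfusionSeries(frames, times)
    truth = PhantomTruth(
        labels=ScalarVolume(grid, labels.astype(float)),
        true_fields=true_fields,
        true_tdc_params=dict(config.enhancement),
        reference_index=ref,
        seed=config.seed,
    )
    return series, truth
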