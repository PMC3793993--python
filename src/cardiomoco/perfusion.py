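"""Perfusion quantification: time-density curves, parameter maps, noise/CNR, dose.

Conventions follow dynamic-CT perfusion reading practice: image noise is
the standard deviation of HU inside a myocardial reference region
(population SD); CNR is the mean HU of an ROI divided by that noise; peak
enhancement (PE) is the per-voxel maximum rise above a pre-contrast
baseline frame; time-to-peak (TTP) is the acquisition time of that
maximum; effective dose is DLP times a chest conversion coefficient
k = 0.014 mSv/(mGy*cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import PerfusionSeries, ROIMask, ScalarVolume, _check_same_grid

__all__ = [
    "fit_gamma_variate",
    "TimeDensityCurve",
    "PerfusionMap",
    "NoiseReport",
    "DoseRecord",
    "extract_tdc",
    "peak_enhancement_map",
    "time_to_peak_map",
    "image_noise",
    "cnr",
    "noise_reduction_percent",
    "effective_dose",
]


@dataclass
class TimeDensityCurve:
    """Per-frame mean and SD of HU inside one ROI, against acquisition time."""

    times_s: np.ndarray
    mean_hu: np.ndarray
    sd_hu: np.ndarray
    roi_label: str
    n_voxels: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.mean_hu = np.asarray(self.mean_hu, dtype=float)
        self.sd_hu = np.asarray(self.sd_hu, dtype=float)
        if not (len(self.times_s) == len(self.mean_hu) == len(self.sd_hu)):
            raise ValueError("times, means and SDs must have equal length")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")

    def max_frame_jump_hu(self) -> float:
        """Largest absolute frame-to-frame change of the mean curve.

        Motion spikes ("false peaks") in an uncompensated series show up
        as large values here; compensation should shrink it.
        """
        return float(np.max(np.abs(np.diff(self.mean_hu))))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "mean_hu": self.mean_hu,
                "sd_hu": self.sd_hu,
                "n_voxels": self.n_voxels,
            }
        )


@dataclass
class PerfusionMap:
    kind: str  # "peak_enhancement" (HU) or "time_to_peak" (seconds)
    values: ScalarVolume
    baseline_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("peak_enhancement", "time_to_peak"):
            raise ValueError(f"unknown map kind {self.kind!r}")


@dataclass
class NoiseReport:
    noise_hu: float
    cnr: float
    roi_label: str
    myocardium_label: str


@dataclass
class DoseRecord:
    dlp_mgy_cm: float
    k_msv_per_mgy_cm: float
    effective_dose_msv: float


def extract_tdc(series: PerfusionSeries, roi: ROIMask) -> TimeDensityCurve:
    """Time-density curve: per-frame mean and SD of HU inside the ROI."""
    _check_same_grid(series.grid, roi.grid)
    data = series.as_array()[roi.mask]  # (n_voxels, n_frames)
    return TimeDensityCurve(
        times_s=series.times_s.copy(),
        mean_hu=data.mean(axis=0),
        sd_hu=data.std(axis=0),
        roi_label=roi.label,
        n_voxels=roi.n_voxels,
    )


def peak_enhancement_map(
    series: PerfusionSeries, baseline_index: int = 0
) -> PerfusionMap:
    """Per-voxel maximum HU rise above the baseline (pre-contrast) frame.

    Voxels that never exceed their baseline value are clipped to 0, so the
    map is non-negative everywhere enhancement occurred.
    """
    if not 0 <= baseline_index < series.n_frames:
        raise ValueError("baseline_index out of range")
    data = series.as_array()
    pe = np.max(data - data[..., baseline_index : baseline_index + 1], axis=-1)
    np.clip(pe, 0.0, None, out=pe)
    return PerfusionMap("peak_enhancement", ScalarVolume(series.grid, pe), baseline_index)


def time_to_peak_map(series: PerfusionSeries, baseline_index: int = 0) -> PerfusionMap:
    """Acquisition time (s) of the per-voxel maximum; ties take the earliest frame."""
    if not 0 <= baseline_index < series.n_frames:
        raise ValueError("baseline_index out of range")
    data = series.as_array()[..., baseline_index:]
    peak_idx = baseline_index + np.argmax(data, axis=-1)  # first max wins ties
    ttp = series.times_s[peak_idx]
    return PerfusionMap("time_to_peak", ScalarVolume(series.grid, ttp), baseline_index)


def image_noise(volume: ScalarVolume, myocardium: ROIMask) -> float:
    """Image noise: population SD of HU inside the myocardial reference region."""
    _check_same_grid(volume.grid, myocardium.grid)
    if myocardium.n_voxels < 2:
        raise ValueError("noise SD needs at least 2 voxels in the myocardium ROI")
    return float(np.std(volume.values[myocardium.mask]))


def cnr(volume: ScalarVolume, roi: ROIMask, noise_hu: float) -> float:
    """Contrast-to-noise ratio: mean HU inside the ROI divided by image noise."""
    if noise_hu <= 0:
        raise ValueError("noise_hu must be > 0")
    _check_same_grid(volume.grid, roi.grid)
    return float(np.mean(volume.values[roi.mask])) / float(noise_hu)


def noise_reduction_percent(noise_before: float, noise_after: float) -> float:
    """Relative noise reduction, in percent of the 'before' level."""
    if noise_before <= 0:
        raise ValueError("noise_before must be > 0")
    return 100.0 * (noise_before - noise_after) / noise_before


def fit_gamma_variate(tdc: TimeDensityCurve) -> "GammaVariateParams":
    """Least-squares fit of a gamma-variate bolus model to a time-density curve.

    Returns the fitted enhancement parameters (baseline, amplitude = peak
    enhancement, onset delay t0 and shape alpha, beta).  Initial values are
    derived from the curve itself (baseline from the first sample, peak
    from the maximum), so the fit is deterministic.
    """
    from .phantom import GammaVariateParams, gamma_variate

    t = tdc.times_s
    y = tdc.mean_hu
    i_peak = int(np.argmax(y))
    baseline0 = float(y[0])
    amp0 = max(float(y[i_peak] - baseline0), 1e-3)
    t_peak0 = float(t[i_peak])
    t0_0 = max(min(0.5 * t_peak0, t_peak0 - 1.0), 0.0)
    alpha0, beta0 = 2.5, max((t_peak0 - t0_0) / 2.5, 0.5)

    def model(tt, baseline, amp, t0, alpha, beta):
        return gamma_variate(tt, baseline, amp, t0, alpha, beta)

    lower = [-200.0, 0.0, 0.0, 0.05, 0.05]
    upper = [500.0, 2000.0, float(t[-1]), 20.0, 60.0]
    p0 = np.clip([baseline0, amp0, t0_0, alpha0, beta0], lower, upper)
    popt, _ = curve_fit(model, t, y, p0=p0, bounds=(lower, upper), maxfev=20000)
    return GammaVariateParams(
        baseline_hu=float(popt[0]),
        amplitude_hu=float(popt[1]),
        t0_s=float(popt[2]),
        alpha=float(popt[3]),
        beta_s=float(popt[4]),
    )


def effective_dose(dlp_mgy_cm: float, k: float = 0.014) -> DoseRecord:
    """Effective dose estimate: DLP (mGy*cm) times the chest coefficient k (mSv/(mGy*cm))."""
    if dlp_mgy_cm < 0:
        raise ValueError("DLP must be >= 0")
    return DoseRecord(
        dlp_mgy_cm=float(dlp_mgy_cm),
        k_msv_per_mgy_cm=float(k),
        effective_dose_msv=float(dlp_mgy_cm) * float(k),
    )
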