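"""Generate the synthetic dynamic cardiac phantom and inspect its curves.

Builds a 15-frame perfusion series with a hypoperfused sector, motion and
noise, then prints the peak of each tissue class's time-density curve.
The true lesion enhancement is lower and later than normal myocardium
(delayed, decreased enhancement) — but note how motion and noise distort
the raw curves: on spike frames a small ROI catches neighbouring tissue
or the bright blood pool, so the raw lesion peak can land at the wrong
time entirely.  Motion compensation (see example 03) is what makes these
curves quantifiable.
"""

import numpy as np

from cardiomoco import PhantomConfig, extract_tdc, generate_phantom
from cardiomoco.validation import series_grid

config = PhantomConfig(grid=series_grid(), seed=42)
series, truth = generate_phantom(config)

print(f"series: {series.n_frames} frames on {series.grid.shape}, "
      f"spacing {tuple(round(s, 2) for s in series.grid.spacing)} mm")
print(f"times (s): {series.times_s}")
print(f"reference frame (zero true motion): {truth.reference_index}")

for cls in ("blood_pool", "myocardium", "lesion"):
    roi = truth.label_mask(cls, erode_voxels=1)
    tdc = extract_tdc(series, roi)
    peak = tdc.mean_hu.max()
    t_peak = series.times_s[np.argmax(tdc.mean_hu)]
    print(f"{cls:12s}: {roi.n_voxels:5d} voxels, "
          f"peak {peak:6.1f} HU at t = {t_peak:4.1f} s "
          f"(true peak time {truth.true_tdc_params[cls].peak_time_s:.1f} s)")
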