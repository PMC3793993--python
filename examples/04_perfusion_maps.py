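"""Peak-enhancement and time-to-peak maps, plus dose arithmetic.

Processes a phantom series end to end, computes the per-voxel PE (HU rise
above the pre-contrast baseline) and TTP (time of the maximum) maps, and
compares their values inside the normal and hypoperfused regions: the
lesion should show lower PE and later TTP.  Also demonstrates the
effective-dose estimate from a dose-length product.
"""

import numpy as np

from cardiomoco import (
    PhantomConfig,
    effective_dose,
    generate_phantom,
    motion_compensate_series,
    peak_enhancement_map,
    spatiotemporal_pipeline,
    time_to_peak_map,
)
from cardiomoco.validation import series_grid

series, truth = generate_phantom(PhantomConfig(grid=series_grid(), seed=42))
compensated, _ = motion_compensate_series(series)
filtered = spatiotemporal_pipeline(compensated)

pe = peak_enhancement_map(filtered, baseline_index=0)
ttp = time_to_peak_map(filtered, baseline_index=0)

for cls in ("myocardium", "lesion"):
    mask = truth.label_mask(cls, erode_voxels=1).mask
    print(f"{cls:12s}: mean PE = {pe.values.values[mask].mean():6.1f} HU, "
          f"median TTP = {np.median(ttp.values.values[mask]):5.1f} s")

dose = effective_dose(dlp_mgy_cm=507.0, k=0.014)
print(f"effective dose for DLP 507 mGy*cm: {dose.effective_dose_msv:.1f} mSv")
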