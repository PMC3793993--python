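"""Three-arm experiment: original vs motion-compensated vs fully filtered.

Generates the lesioned arrhythmia phantom, runs motion compensation and
spatio-temporal filtering, and prints image noise (myocardial HU standard
deviation, averaged over frames), the lesion-ROI contrast-to-noise ratio
and the largest frame-to-frame jump of the subendocardial time-density
curve.  Noise should fall and CNR rise from arm to arm, and compensation
should suppress the motion spikes (false peaks) in the TDC.
"""

from cardiomoco.validation import three_arm_study

study = three_arm_study(noise_sd_hu=10.0, seed=11)

print(f"{'arm':<14s}{'noise (HU)':>12s}{'CNR':>8s}")
for arm in ("original", "compensated", "filtered"):
    print(f"{arm:<14s}{study[f'noise_{arm}_hu']:>12.2f}{study[f'cnr_{arm}']:>8.2f}")
print()
print(f"TDC max frame jump, raw:         {study['tdc_max_jump_raw_hu']:.1f} HU")
print(f"TDC max frame jump, compensated: {study['tdc_max_jump_compensated_hu']:.1f} HU")
print(f"spike suppression ratio:         {study['tdc_jump_ratio']:.2f}x")
print(f"noise reduction (i -> iii):      {study['noise_reduction_percent']:.1f}%")
print(f"CNR improvement (i -> iii):      {study['cnr_improvement_factor']:.2f}x")
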