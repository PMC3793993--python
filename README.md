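# cardiomoco

Motion compensation, spatio-temporal denoising and perfusion
quantification for **dynamic (time-resolved) cardiac CT**.

Dynamic CT myocardial perfusion imaging acquires a short series of
ECG-triggered volumes while a contrast bolus passes through the heart; the
mean attenuation of a myocardial region over time (the time-density curve,
TDC) carries the perfusion information. Two things corrupt that signal:
cardiac/respiratory motion between acquisitions — especially under
arrhythmia, where a fixed ROI can land on the contrast-filled ventricular
lumen and produce spike-like false peaks — and the high image noise of
low-dose acquisitions. This package implements the standard remedy chain:

1. **Elastic registration** of adjacent time frames: minimise
   `J[u] = ½∫(T(x+u) − R)² + α∫( μ/4 Σ(∂ⱼuₖ+∂ₖuⱼ)² + λ/2 (div u)² )`
   via the Euler–Lagrange system (Navier–Lamé operator + intensity force),
   finite differences with Neumann boundaries, conjugate-gradient inner
   solves, a multi-resolution pyramid, and a 0.05 mm convergence rule.
2. **Motion model**: pairwise fields concatenated toward a reference frame
   (`u = inner + outer∘(id+inner)`), then every frame warped into that
   frame's geometry.
3. **Spatio-temporal filtering**: per-frame 3D bilateral (edge-preserving)
   smoothing, then a per-voxel 3-point temporal moving average with
   weights (0.25, 0.5, 0.25).
4. **Quantification**: TDCs, peak-enhancement (PE) and time-to-peak (TTP)
   maps, image noise (myocardial HU standard deviation), CNR
   (ROI mean / noise), and effective dose (DLP × k, k = 0.014
   mSv·mGy⁻¹·cm⁻¹).

A configurable **synthetic dynamic cardiac phantom** (annular myocardium
with a hypoperfused sector, analytic gamma-variate enhancement per tissue,
smooth motion plus extrasystole-like translation spikes, Gaussian noise,
full ground truth) is included and drives the whole validation suite.
See `docs/methods.md` for the model details and design decisions.

## Worked example

```bash
python examples/03_three_arm_pipeline.py
```

generates the lesioned arrhythmia phantom (15 frames, 48×48×10 voxels,
10 HU noise), motion-compensates it, applies the spatio-temporal filter,
and prints:

```
arm             noise (HU)     CNR
original             15.40    5.98
compensated          12.55    7.34
filtered             10.29    9.11

TDC max frame jump, raw:         48.4 HU
TDC max frame jump, compensated: 14.8 HU
spike suppression ratio:         3.27x
noise reduction (i -> iii):      33.2%
CNR improvement (i -> iii):      1.52x
```

Reading it: the three arms are (i) original, (ii) motion-compensated,
(iii) compensated + filtered. Image noise (the HU standard deviation in
the myocardium, averaged over frames) falls and the lesion-ROI
contrast-to-noise ratio rises from arm to arm; the largest frame-to-frame
jump of the subendocardial TDC — the motion-spike artifact — shrinks more
than threefold after compensation. The other examples cover phantom
generation (`01`), single-pair registration against a known 3 mm warp
(`02`, mean endpoint error ≈ 0.99 mm), and PE/TTP maps plus dose
arithmetic (`04`).

The same pipeline is scriptable from the shell:

```bash
cardiomoco phantom --out-series series.nii.gz --out-labels labels.nii.gz --seed 42
cardiomoco compensate --series series.nii.gz --out aligned.nii.gz --reference middle
cardiomoco filter --series aligned.nii.gz --out filtered.nii.gz
cardiomoco maps --series filtered.nii.gz --out-pe pe.nii.gz --out-ttp ttp.nii.gz
```

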