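# Methods

`cardiomoco` implements a processing chain for dynamic (time-resolved)
contrast-enhanced cardiac CT: pairwise elastic motion estimation between
adjacent time frames, concatenation of the pairwise fields into a common
reference frame, per-frame edge-preserving spatial filtering followed by a
3-point temporal moving average, and the downstream perfusion
quantification (time-density curves, peak-enhancement and time-to-peak
maps, image noise, CNR, effective dose). A synthetic dynamic cardiac
phantom with complete ground truth is part of the package and backs every
quantitative claim the tests make.

## Registration model

Given a reference frame R and a template frame T on a shared voxel grid,
the displacement field u (stored in physical mm, one 3-vector per voxel)
minimises

    J[u] = SSD(R, T; u) + alpha * S[u]

with `SSD = 1/2 ∫ (T(x + u(x)) − R(x))² dx` and the linear-elastic
potential

    S[u] = ∫ mu/4 * Σ_jk (∂_j u_k + ∂_k u_j)² + lambda/2 * (div u)² dx.

The Euler–Lagrange condition couples the Navier–Lamé operator
`mu Δu + (mu+lambda) ∇(div u)` with the intensity force
`f = −(T(x+u) − R)·∇T(x+u)`. The solver runs an outer fixed-point
iteration: at the current u the force is evaluated and a linear elastic
system is solved for the update δu by conjugate gradients; the iteration
stops when the maximum voxelwise update falls below 0.05 mm. Everything is
embedded in a coarse-to-fine pyramid (factor-2 downsampling with 1-voxel
Gaussian pre-smoothing); by default the finest level receives the
upsampled coarse solution without further optimisation, trading a little
accuracy for a large speedup. All steps are deterministic.

### Numerical choices

* **Two discretisations of the elastic operator.** The pointwise operator
  (`elastic_operator_apply`) uses second-order central differences with
  edge-replicated (Neumann) ghost values — the textbook stencil, verified
  against an independently assembled dense matrix. That stencil, however,
  is *not symmetric at the boundary* (the mixed ∂_j∂_k terms with clamped
  ghosts have no matching transpose), so it cannot back a conjugate-
  gradient solve. The linear systems therefore use the Galerkin (energy)
  assembly `K = mu Σ_j D_jᵀD_j + (mu+lambda) CᵀC` (D_j forward
  differences, C the central-difference divergence with zero boundary
  rows), which is symmetric positive semidefinite by construction and
  agrees with the negated Navier–Lamé operator to second order in the
  interior. A Tikhonov shift of 1e-6 times the stencil's diagonal scale
  removes the constant-field null space.
* **Rigid-translation mode.** The elastic potential is translation-
  invariant, so the global translation component of the update carries no
  regulariser curvature; with only the tiny Tikhonov shift the
  noise-driven net force would be amplified into enormous spurious shifts
  (hundreds of mm were observed). The solver therefore projects the
  constant mode out of each CG solve (the operator maps the zero-mean
  subspace to itself exactly) and handles translation by its natural
  Gauss–Newton step from the SSD curvature — a 3×3 solve of
  `(Σ g gᵀ) c = Σ (R − T(x+u)) g` with `g = ∇T(x+u)` — trust-capped at
  5 mm per outer iteration so a rigid step can never push the image out of
  overlap (edge clamping would make the SSD spuriously small there).
* **Step control.** If an update increases J it is halved, up to 8 times;
  if no fraction of the step decreases J the level terminates. CG is
  declared divergent (an error naming level and iteration) only when its
  residual both rises over 10 consecutive iterations *and* exceeds twice
  its initial norm — for ill-conditioned SPD systems the plain 2-norm
  residual legitimately rises for stretches while the energy-norm error
  falls, so the bare streak rule alone would be a false positive.
* **Parameters.** `lame_mu = 1` with Poisson ratio 0.01 (λ ≈ 0.0204 via
  the standard (E, ν) relations): a stiff, nearly uncoupled elastic model
  that resists the false deformations driven by contrast inflow.
  `reg_weight = 3000` balances SSD (in HU²) against the regulariser; it
  was calibrated on the phantom as the smallest weight for which
  identical-image registration stays below the convergence tolerance while
  a known smooth 3 mm warp is still recovered to well under 1 mm —
  absolute weights do not transfer between intensity scales, so a
  phantom-based calibration is the only meaningful definition. Pyramid
  depth defaults to 3 levels.

## Motion model

Pairwise fields are estimated between temporally adjacent frames only,
always oriented toward a designated reference frame (default: the middle
frame, which halves the worst-case chain length); the field taking frame i
to the reference is the composition
`u(x) = inner(x) + outer(x + inner(x))` accumulated along the chain, and
each frame is warped by trilinear interpolation (values never leave the
frame's intensity range). Adjacent-pair estimation is deliberate: adjacent
frames are the most similar pair available, and the elastic regulariser is
the stated mitigation for the residual dissimilarity caused by contrast
inflow.

## Spatio-temporal filtering

The spatial stage is a 3D bilateral filter per frame: Gaussian domain
kernel (default sigma 2 mm, radius 2 voxels) times a Gaussian range kernel
in HU (default sigma 30 HU). It reduces noise in homogeneous regions while
preserving tissue boundaries; with range sigma → ∞ it reduces exactly to
its truncated Gaussian domain kernel (tested). The published filter it
stands in for is specified only by that contract — edge-preserving
smoothing applied independently per frame — so a bilateral filter is the
faithful, non-proprietary realisation; its parameters are fully exposed.

The temporal stage is a per-voxel 3-tap weighted moving average with
weights (0.25, 0.5, 0.25), applied after motion compensation. At the
series endpoints the missing tap is dropped and the remaining weights are
renormalised (unbiased on constants); edge replication is available as an
alternative. For iid noise the interior variance factor is exactly
0.25² + 0.5² + 0.25² = 0.375. Stage order is spatial-then-temporal, with
the order exposed as a switch.

## Perfusion quantification

* **TDC**: per-frame mean and SD of HU inside an ROI, against acquisition
  time.
* **PE map**: per voxel, max over frames of (value − baseline value),
  negatives clipped to zero; baseline defaults to frame 0 (pre-contrast).
* **TTP map**: acquisition time of the per-voxel post-baseline maximum,
  earliest frame on ties.
* **Image noise**: population SD (divide by n) of HU inside the
  myocardial reference region.
* **CNR**: ROI mean HU divided by image noise — the literal reading-room
  definition; a difference-based CNR (lesion vs remote contrast over
  noise) is a reasonable alternative but is not what the source protocol
  describes, so it is not implemented.
* **Effective dose**: DLP × k with the chest coefficient
  k = 0.014 mSv/(mGy·cm).

For three-arm comparisons the pipeline reports, per arm, the myocardial
noise averaged over all frames (default). A single-frame report is
available (`noise_frame="peak"` or an index) but is degenerate whenever
the chosen frame coincides with the compensation reference frame, which is
returned untouched by construction.

## The synthetic phantom

The phantom emulates a 15-acquisition, alternate-cardiac-cycle stress
perfusion scan (one frame every 2 s, 250 mm in-plane field of view, 3 mm
slices): an ellipsoid-tapered annular "myocardium" around a blood-pool
core, with an optional angular-sector lesion of configurable transmural
depth. Each class follows an analytic, peak-normalised gamma-variate
curve — `baseline + A·((t−t0)/(αβ))^α · exp(α − (t−t0)/β)` — so the
configured amplitude *is* the true peak enhancement: blood gets a fast,
high first-pass input (A = 300 HU, peak ≈ 6.5 s), myocardium a gentle
tissue response (A = 80 HU, peak ≈ 14 s), and the lesion a delayed
(+4 s), decreased (A = 45 HU) variant. A frozen smooth intra-tissue
texture (12 HU SD) rides with the tissue; the background is left clean so
its SD measures pure noise. Per-frame motion is a smooth sinusoidal field
(default 3 mm amplitude, 120 mm spatial wavelength, sinusoidal phase over
frames, zero at the reference frame) plus 6 mm translation spikes on
designated "extrasystole" frames; frames are synthesised by warping with
the numerically inverted truth field, then adding fresh Gaussian noise
(default 10 HU SD). Identical seed and configuration reproduce the series
bit for bit.

Two generator choices deserve emphasis. The z-taper exists because a
z-uniform cylinder makes through-plane motion unobservable, and the solver
then invents spurious z-shifts from contrast-inflow forces. And the
tissue-class curves must be *slower* than the blood input: myocardial
enhancement in dynamic CT rises over 10–20 s, so the natural frame-to-
frame rise (~15–20 HU) stays well below motion-spike artifacts
(50–100 HU) — a phantom whose tissue enhances at blood speed buries the
motion artifact it is supposed to expose under its own bolus rise.

**What the phantom does not emulate**: projection-domain physics (beam
hardening, photon starvation, structured CT noise), anatomical context
(lungs, chest wall, papillary muscles), ECG-phase-dependent deformation,
and partial-volume effects beyond trilinear resampling. Passing the
phantom studies therefore shows the algorithms are correctly implemented
and behave as designed under known, controllable conditions — not that
clinical accuracy on patient data is guaranteed.

## Validation studies and problem sizes

The `validation` module fixes the study conditions: single-pair
registration studies (identity, known 3 mm warp) run on a 64³ grid;
dynamic-series studies (the three-arm experiment at 5/10/20 HU noise, the
enhancement-parameter recovery) run 15 frames on a 48×48×10 grid, which
keeps a full three-arm experiment in the tens of seconds. The three-arm
TDC spike metric uses a small subendocardial spherical ROI in the lesion
sector — the clinically read region, and the geometry in which
uncompensated spike frames catch the contrast-filled lumen and produce
false peaks.

## Known limitations

* SSD similarity is systematically biased by contrast inflow: around
  bolus arrival, adjacent frames differ by >100 HU in the blood pool and
  the pre-arrival frames lack the inner-wall edge entirely. The resulting
  per-pair bias is correlated along the chain, so concatenated fields
  degrade toward the chain ends (several mm at 5–7 compositions from the
  reference, versus ~1 mm adjacent to it). The stiff elastic model limits
  but does not remove this; similarity measures robust to intensity
  change are out of scope here.
* The gamma-variate onset time t0 is weakly identifiable from 2-s-sampled,
  filtered curves (it trades off against the shape parameters); fits
  recover the lesion-vs-normal *relative* delay well, but absolute onsets
  shift early by a few seconds.
* The bilateral filter is a contract-level stand-in for the published
  edge-preserving filter it replaces; matching that filter's exact output
  is a non-goal.
* Registration assumes the whole field of view moves smoothly; sliding
  interfaces (lung/chest wall) violate this and are absent from the
  phantom.
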