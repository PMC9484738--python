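# Methods

## Model

A poroelastic sample under a step of uniaxial compressive stress σ₀
behaves as an incompressible elastic solid at t = 0⁺ (effective
Poisson's ratio near 0.5) and as a drained elastic solid at steady
state.  Between the two, the strain at every point is modelled as a
single first-order relaxation

    s(t) = η + (α − η) · exp(−t/τ),

where α is the instantaneous strain, η the steady-state strain and τ
the strain time constant.  When vascular drainage dominates
interstitial flow (χ ≫ k/a², with χ = L_p·S/V the microfiltration
coefficient, k the interstitial permeability and a the inclusion
radius), the time constant is

    τ = 1 / (H_A · L_p · S/V),        H_A = E(1−ν) / ((1−2ν)(1+ν)).

The package's forward model replaces a finite-element poroelastic
solution with this analytic structure: the spatial fields α and η come
from the Eshelby equivalent-inclusion solution for an ellipsoidal
inhomogeneity under remote uniaxial stress — evaluated at the drained
(E, ν) for η and at the same E with ν_eff = 0.499 in both regions for
α — and each region relaxes with its own τ.  This is exact for the
temporal law (by construction) and for the steady spatial fields of an
unbounded medium; it omits finite-boundary corrections, pore-pressure
diffusion within regions, and any multi-exponential behaviour.  The
choice of "same E, ν_eff = 0.499" for the undrained state is a
documented stand-in (undrained stiffening is not modelled); one
consequence is that the far-field axial strain has no transient, since
uniaxial stress gives ε_zz = σ₀/E at any ν.

Sign convention throughout: axial strain is stored compression-positive
and lateral strain expansion-positive, so creep curves are monotone and
the lateral/axial ratio is a positive effective Poisson's ratio.

## Parameter estimation pipeline

1. **Temporal fitting (variable projection).**  For fixed τ the model
   is linear in (η, α−η); the residual minimised over τ on a log-spaced
   bracket of 160 points spanning 0.1–10× the window, refined by
   golden-section search.  Curves whose dynamic range falls below a
   tolerance are flagged degenerate (η = mean, τ = NaN).  Fitted τ
   values above 100 s inside the inclusion are outliers and replaced by
   the in-mask median; for those pixels the steady state is re-solved
   linearly with the replacement τ, because a runaway τ carries an
   equally runaway extrapolated η.
2. **EOF denoising.**  The pixels × time strain matrix is truncated to
   its leading singular vectors.  Default rank 3 (a noise-free
   two-region movie has rank ≤ 3: a constant and two exponential
   shapes).  For strains estimated from tracked RF data the pipeline
   retains 8 modes: tracking artefacts carry their own temporal
   dynamics, and truncating below the effective rank folds the creep
   transient into an artefact mode and biases τ upward by tens of
   percent.  The retained-energy fraction is reported so the choice can
   be audited.
3. **Window-of-observation convention.**  Short windows are defined as
   multiples of a *pilot* time constant, the median in-mask τ of the
   full-record fit (the underlying τ is unknown in practice).  Windows
   reaching the record length are capped at 95% of it.
4. **Background moduli.**  E_b = σ₀/ε_zz and ν_b = ε_rr/ε_zz from the
   steady states of ROI-mean background curves.  The ROI is a shallow
   band above the inclusion, where displacements (and therefore
   tracking errors) are smallest.  Short-window background steady
   states are re-solved linearly with the full-record background τ
   held fixed; a free exponential fitted to a transient-free noisy
   curve extrapolates arbitrarily far.
5. **Inclusion moduli (Eshelby inversion).**  Measured strains enter as
   the normal components (e11, e22, e33), with the unobserved
   elevational component set equal to the lateral one by axisymmetry.
   The geometric eigenstrain S⁻¹(ε_in − ε⁰) is matched against the
   material eigenstrain from the equivalency
   [(C_i − C_b)S + C_b]ε* = (C_b − C_i)ε⁰; the squared mismatch
   (normalised by |ε⁰|²) is minimised over E_i ∈ [0.05, 50]·E_b,
   ν_i ∈ [0.01, 0.499] with 5 fixed-seed multi-starts of L-BFGS-B in
   (log E_i/E_b, ν_i).  Estimates that end on the box boundary are
   flagged.  Per-pixel map inversion caches identical strain pairs, so
   piecewise-uniform maps cost a single minimisation.
6. **Transport.**  L_p = 1/(τ·H_A(E_i, ν_i)·S/V) per pixel after the
   outlier rule; S/V either known (simulations use 20,000 m⁻¹) or from
   the tumour-volume regression S/V[cm⁻¹] = 10·54.68·V_t^(−0.2021)
   with V_t = (4/3)π·l₁²·l₂ from the mask's best-fit ellipse.  The API
   takes S/V strictly in m⁻¹; the cm⁻¹ → m⁻¹ factor of 100 lives in
   the explicit converter.  Background permeability output is opt-in,
   since χ ≫ k/a² may fail in normal tissue.

Percent relative error (PRE) between a short-window estimate ρ_s and
the full-duration estimate ρ_f is the mean over inclusion pixels of
100·|ρ_f − ρ_s|/ρ_f.  The baseline is deliberately the full-record
*estimate*, not the ground truth; the truth error of the full-record
estimate is reported separately in every experiment report.  Pixels
whose full-record inversion was boundary-flagged are excluded from the
mean (count logged): they contribute no usable reference denominator.
Short-window failures are *not* excluded — they are what PRE measures.
Reports also carry a scalar route (mask-mean curves fitted and inverted
once), which is the recommended summary when per-pixel maps are noisy.

## Ultrasound simulation and tracking

RF frames are synthesised with a separable convolution model: point
scatterers (10 per resolution cell, uniform positions, standard-normal
amplitudes) are splatted bilinearly onto the line/sample grid and
convolved with a PSF that is a Gaussian-enveloped cosine axially
(−6 dB spectral width = 0.5·6.6 MHz) and a Gaussian laterally (−6 dB
width = 1 mm beamwidth); Gaussian noise sets the per-frame SNR.
Bilinear splatting matters: binning scatterers to the nearest node
quantises the sub-sample displacement phase and aliases into strain
artefacts an order of magnitude above everything else.

Tracking is two-step.  A dynamic-programming Viterbi pass per A-line
(blocks of 16 samples, L1 continuity penalty between neighbouring
blocks and a soft coupling to the previous line's path) gives integer
offsets; the integer field is low-pass filtered and used to warp the
post frame, and Horn–Schunck optical flow estimates the smooth
sub-sample residual.  The flow step is iterated three times with
re-warping — single-pass brightness-constancy linearisation is biased
on oscillatory RF — and the axial image gradient is computed spectrally
(a central difference underestimates the derivative at the carrier by
sinc(k) and inflates the flow by ~20%).  Each creep frame is tracked
directly against the undeformed reference frame: the creep transient
changes the strain by well under a percent after the elastic jump, so
reference-frame decorrelation stays low, while composing consecutive
incremental estimates would random-walk the weak lateral displacement.
Strains are moving least-squares slopes (49 samples axially, 5 lines
laterally) smoothed by a scalar random-walk Kalman filter, then
resampled to a 0.5 mm analysis grid and lightly smoothed spatially.

## Study conditions and problem sizes

The phantom library mirrors the study structure: four spherical and
two spheroidal inclusions (7.5 mm diameter spheres; 7.5 mm lateral ×
5 mm axial spheroids) in a 20 × 40 mm plane, S/V = 20,000 m⁻¹, 1 kPa
creep stress, 60 s records at 0.1 s (120 s at 0.2 s for the 30.25 s
time-constant sample), background 10 kPa / ν 0.3, stiffness contrasts
0.5–4× and inclusion time constants 5–30.25 s.  The exact per-sample
material values are this package's own documented defaults, chosen to
satisfy those printed constraints.  The evaluation suite analyses the
phantoms at 0.2 mm pixels; the generator default is 0.1 mm.

The ultrasound-chain experiment is run at a reduced scale: a 20 × 20 mm
field, ~60 frames at 1 s spacing, and a single spherical phantom with
E_b = 25 kPa (≈4% strain at 1 kPa — inside the 1–5% range elastography
targets, and large enough for the weak lateral signal to rise above
speckle-tracking artefact level) and τ = 15 s, making the record 4 time
constants with ~30 frames inside a 2-TC window.

## What the synthetic data do and do not show

The generator's temporal law is exactly the model the fitter assumes,
so noise-free experiments test the pipeline's numerics, not model
misspecification: their near-zero PREs demonstrate self-consistency
and correct plumbing.  The noisy arms (strain-domain noise, and the
full RF chain) probe estimator robustness, but real tissue adds
heterogeneity, multi-exponential relaxation, boundary effects and
physiological motion that none of the arms emulate.  In the RF arm the
per-pixel lateral strain signal is comparable to quasi-static
speckle-tracking artefacts at these strain levels; per-pixel
Poisson's-ratio and permeability maps are therefore unstable at the
scaled frame count (the paper-scale experiments use ten times as many
frames per window), while Young's modulus and all ROI-level summaries
remain well behaved.  This limitation is visible in the reported
ultrasound-chain PREs and is the expected scaled-down behaviour, not a
property of the method at full scale.

## Numerical choices

- Spheroid Eshelby tensors use the closed-form I-integrals; within
  10⁻⁴ of aspect ratio 1 they delegate to the sphere expressions (the
  relations divide by a₃² − a₁² and lose all precision closer in).
- The equivalent-inclusion system is solved in the 3 × 3
  normal-component subspace; the full Mandel-notation solve exists in
  the test suite as an independent oracle.
- Variable projection: τ grid of 160 points, 48 golden-section
  iterations; fits are deterministic, as is every simulation given its
  seed (all randomness flows through `numpy.random.default_rng`).
- The DP data cost adds a 10⁻⁶·(|Δa|+|Δl|) tie-break toward zero
  motion, so exact cost ties at edge-padded borders resolve to rest.
- Degenerate inputs: constant strain curves (e.g. the transient-free
  background axial strain) yield η = mean with τ = NaN rather than an
  unstable exponential fit.

## Known limitations

- Single-exponential temporal model only; no stretched or
  multi-exponential relaxation.
- The undrained state is approximated by ν_eff = 0.499 at unchanged E.
- The Eshelby solution assumes an unbounded background; finite-sample
  boundary effects are not represented.
- Lateral strain estimation at 0.3 mm line pitch limits per-pixel
  Poisson's-ratio maps at low applied strain; ROI-level estimates are
  the reliable product of the RF arm.
- No out-of-plane motion, attenuation, or depth-dependent PSF in the
  RF model.
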