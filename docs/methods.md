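# Methods

This note documents the models, numerical choices, and limitations of
`tubepump` — what each stage assumes, how the synthetic phantom encodes
the study conditions, and what passing the test suite does and does not
demonstrate about real data.

## 1. The biomechanical model

A short segment of a valveless heart tube is modelled as a differential
cylindrical volume with axisymmetric wall motion. Two terms govern the
local pressure balance:

* **Wall-movement pressure term.** At one cross-section,
  `p_w(t) = −(μ/A) dA/dt`: expansion (dA/dt > 0) lowers local pressure
  (suction), contraction raises it (pushing). Between the bracketing
  planes the proxy is `G(t) = p_w(L1) − p_w(L3) =
  (1/A₃)dA₃/dt − (1/A₁)dA₁/dt`, with `G > 0` meaning wall motion drives
  forward (L1 → L3) flow. Blood viscosity μ is assumed constant over the
  ~60 µm region and set to 1: only relative dynamics and signs of `G`
  are interpreted, never absolute pressures (which would additionally
  require the flow-profile constant and viscosity the model does not
  measure). Units of `G` are s⁻¹.
* **Viscous resistance.** The opposing resistance scales as `1/A_a`
  with `A_a = (A₁+A₃)/2`. It is reported cycle-normalized to [0, 1]
  (minimum resistance → 0, maximum → 1; fully closed phases are pinned
  to exactly 1). The raw `1/A_a` is floored at one optical resolution
  cell (16 µm², see §4) so closure does not produce infinities.

The analysis never combines the two terms into an absolute pressure
gradient; instead the resistance *gates* the causal analysis: only the
contiguous low-resistance window (`R_norm < 0.1`, the default
threshold) enters the Granger test, because near closure the resistance
term dominates and the pressure–flow relation is not expected to hold.

## 2. Reconstruction

* **Doppler velocimetry.** Axial velocity per pixel is the windowed
  Kasai autocorrelation: lag-one conjugate products of laterally
  adjacent A-scans, summed over an M×N window (default 3×3), scaled by
  `λ f_A / 4π n` with λ = 810 nm, f_A = 68 kHz, n = 1.4 — 3.13 mm/s per
  radian, Nyquist bound 9.84 mm/s. The four-quadrant arctangent is used
  (range ±π): peak blood speeds in this regime exceed the ±π/2 range of
  a single-argument arctangent (±4.9 mm/s), so full-range recovery is
  required. Windows whose accumulated products sit at the numerical
  floor are zeroed and flagged low-confidence.
* **Period estimation.** The heartbeat period is the first dominant
  local maximum of the frame-similarity autocorrelation (Pearson
  correlation of 4×-coarsened log-intensity frames at each lag), with
  parabolic sub-frame refinement. "Dominant" means at least half the
  global autocorrelation maximum beyond the zero-lag lobe — shallow
  ripples in the decorrelation valley must not pass for a heartbeat.
* **Gating.** Each slice's frames are folded into one canonical cycle
  (nearest phase bin; intensity is compounded linearly across cycles
  before conversion to dB, which is what suppresses speckle; Kasai
  velocities are averaged). Adjacent slices are phase-aligned by
  maximizing circular cross-correlation of their folded structural
  stacks, with parabolic sub-bin refinement; *cumulative* fractional
  shifts are rounded per slice so pairwise rounding errors do not
  random-walk along the slice chain. Ties break toward the smallest
  absolute shift. Slices whose estimated periods spread by more than 5%
  abort synchronization.

**Known gating limitation.** Correlation alignment finds the shift that
makes neighbouring slices' dynamics most similar — it aligns wave
crests. A wall wave travelling at speed c therefore loses part of its
true inter-slice phase delay (~slice-step/c per pair) in the
reconstruction. For ventricular conduction speeds (5.5–10 mm/s) this is
≲0.2 phase bins per 10 µm step — small but cumulative; for the slow
outflow-tract wave it is substantial. Consequences: (a) the
gating-recovery check uses a near-synchronous phantom, where recovered
shifts can be compared against the acquisition ground truth; (b) the
ventricle-like scenario encodes the L1/L3 asymmetry as waveform *shape*
differences (which correlation cannot align away), not only as timing
delays. Any correlation-gated 4D reconstruction shares this property.

## 3. Measurement

* **Planes.** L1, L2, L3 lie perpendicular to the tube axis, 30 µm
  apart, ordered with the forward flow; plane images are trilinear
  reslices of the volume. In phantom mode the planes coincide with
  acquisition slice stations, avoiding interpolation between
  independently-aligned slices.
* **Segmentation.** The blood-filled lumen is darker than the wall. One
  threshold per cycle is pooled from all phases (three-class Otsu on the
  ROI; the upper threshold separates blood from wall) — a drifting
  per-phase threshold produced multi-pixel errors at small-lumen phases.
  The below-threshold component containing the image centre, hole-filled,
  is the lumen; components touching the ROI boundary are background.
  When a speckle fade breaches the wall ring and the lumen leaks into
  the background, progressively stronger morphological opening severs
  the leak before the component test. Three replicates perturb the
  threshold by ±5% of the blood–wall class separation, emulating the
  spread of repeated manual segmentation; traces carry mean ± std.
  A lumen below one resolution cell (16 µm²) is recorded as closed.
* **Flow rate.** `V = Σ (v_a / cos θ) · pixel_area` over the lumen mask,
  signed, in µm³/s. Division by cos θ converts the measured axial
  component back to the along-tube speed, which is the correct flux
  density through a plane perpendicular to the tube axis; the
  multiplicative variant is available behind a switch for comparison.
  θ defaults to the phantom's beam-to-tube angle (60°).
* **Peak flow speed.** "Averaged peak blood-flow speed" is defined as
  `max_t |V(t)|/A(t)` at L2 over phases with `A ≥ 25%` of the cycle
  maximum. Speed read through a nearly closed aperture is an
  aperture-transit artifact (and numerically a near-0/0), not transport,
  so those phases are excluded. The phantom scenarios calibrate their
  true in-gate peak speed to this definition.

## 4. The phantom

The phantom provides exact ground truth for every estimated quantity.

* **Kinematics.** `r(z, t) = rest + amp · f(u, z/L) · scale(z)` with
  `u = ((t − z/c)/T) mod 1`; `c` is the activation (conduction) speed.
  Open-fraction profiles are piecewise smoothstep ramps; the
  ventricle-like profile closes for ~20% of the cycle, relaxes slowly
  (0.35 T) and contracts fast (0.14–0.18 T), and morphs along the axis
  from an early-peak upstream shape to a slow-filling downstream shape
  with a brief rapid-filling surge — the source of within-window
  pressure-gradient dynamics. A seeded multiplicative roughness field
  (5% of radius, 30 ms / 20 µm correlation) emulates trabeculation and
  beat-to-beat irregularity of real area traces; without it the folded
  series are smooth ramps whose "causality" is an artifact of
  extrapolability rather than of innovations.
* **Flow.** Incompressible: `Q(z,t) = Q(z₀,t) − ∫ ∂A/∂t dz′`, integrated
  on a 4× z-oversampled analytic radius field. When any cross-section is
  closed, the inlet flux is fully determined by requiring zero flux
  through the plug (`consistent_inlet_flux`); a free drive applies only
  while the tube is open. Velocity profiles: plug or Poiseuille
  (centerline = 2× mean).
* **Scenario couplings.** Ventricle-like: the flux at L2 is a constant
  gain times the *band-limited* pressure-gradient proxy (sampled at the
  volume rate and smoothed exactly as the measurement smooths it —
  flow inertia low-passes the response) delayed by 20 ms, tapered off
  below 15% of peak open area, plus a seeded smooth nuisance component
  (30% of the response spread) standing in for flow sources the local
  two-plane proxy cannot see. In-gate peak speed calibrated to 4.9 mm/s
  against a 7 mm/s activation speed. Outflow-like: a passive
  fast-open/slow-close wave at 0.6 mm/s, with an ejection flux pulse
  (peak 5.9 mm/s) centred in the fully open part of the cycle —
  flow leads the wall wave and is not caused by it.
* **Rendering.** Frames are complex speckle images: bright wall annulus
  (16 µm thick — a myocardium-plus-jelly composite; thinner walls leak
  speckle fades through the ring), dimmer blood, dark background, at
  1 µm pixels over 128×128 for the scenario phantoms (speckle grain
  2×3 µm, set by the imaging resolution, not the pixel pitch). Region
  speckle is a spatially correlated circular complex Gaussian field
  evolving as AR(1) in time (tissue decorrelation 15 frames, blood
  2 frames — moving erythrocytes rearrange fast), which is what makes
  cycle compounding effective, as in living tissue. Moving blood
  multiplies column j by `exp(i Σ_{j′≤j} Δφ(j′))` with
  `Δφ = 4π n v_axial/(λ f_A)`, so the lag-one autocorrelation recovers
  the imposed phase exactly; additive complex noise sets the SNR
  (default 30 dB re. wall). Imposed phases beyond ±π are rendered
  wrapped and flagged `doppler_aliasing` in the metadata; the
  ventricle-like scenario genuinely exceeds the Nyquist speed during
  early-filling jets through the barely open lumen (excluded from both
  the peak-speed gate and — mostly — the causality window).
* **What the phantom does not model.** No wave-optics propagation,
  confocal PSF, attenuation/shadowing, bulk motion, dispersion,
  non-axisymmetric lumens, trabecular geometry, or beat-to-beat period
  variability (the folded cycle is strictly periodic).

## 5. Causality

Bivariate Granger per lag order p ∈ {1, 2, 3} (10/20/30 ms at the
100 Hz volume rate): both series de-meaned; restricted model `y_t ~
y_{t−1..t−p}`, unrestricted adds `x_{t−1..t−p}`;
`F = [(RSS_r − RSS_u)/p]/[RSS_u/(T − 2p − 1)]` referred to
`F(p, T−2p−1)` (χ² variant available). One p-value per lag per
direction, matching per-order reporting; no differencing (stationarity
within the short gated window is assumed — a logged caveat); only the
longest contiguous low-resistance run of the single reconstructed cycle
is used, never stitched across masked gaps (lagged regression requires
contiguity). The test is calibrated: under a white-noise null the
rejection rate at α = 0.05 is 5% ± 2% over 1000 replicates, and a
lag-2-coupled pair (gain 0.8, noise 0.1, n = 60) is detected at
p ≤ 0.01 in ≥ 18/20 seeds with the reverse direction silent.

**Single-cycle caveat.** On one folded cycle the series are largely
deterministic curves plus measurement noise. Forward detection then
rides on the wall-motion innovations that propagate into the flow with
the built-in lag; but the *reverse* direction (flow → pressure) can
reach nominal significance in a sizeable minority of seeds, because the
nearly noise-free flow series carries older values of the gradient's
deterministic component, which help "predict" the noisy measured
gradient (an errors-in-variables artifact amplified by the smoothing
filter's moving-average structure). The seed-replicated checks
therefore assert the forward-direction majority and the passive-case
null, not the reverse direction. Interpreting a single cell of a
single-cycle causality table is not recommended; seed (or cycle)
replication is.

**Truth-path replication.** Seed-replicated statistics use
`truth_hemodynamics`: areas and flux read off the phantom's exact
kinematics/flow on the phase grid, perturbed by the noise the imaging
pipeline actually delivers (0.3% of peak area; 5% of peak flow). The
full imaging chain is exercised end-to-end separately; its causality
outcomes are noisier than the truth path (gating flattening and
near-closure aliasing degrade the gradient–flow relation), which is
reported as-is, not hidden.

## 6. Numerical choices

* Savitzky–Golay derivative, window 5, order 2, circular padding
  (cycle-periodic); polynomial-exact for locally quadratic traces.
* Log-intensity floor: 1e−12 of the peak amplitude; all-zero frames map
  to the floor, never −inf.
* Phase-bin assignment: nearest bin; empty bins filled from the nearest
  populated neighbour.
* Relaxation/contraction labelling threshold τ: 2% of the maximal
  |dA/dt|; unlabeled samples join the nearest labelled interval
  circularly, so the intervals always tile the cycle.
* Suction/pushing evidence threshold: 60% sign agreement among
  low-resistance samples of an interval; both mechanisms present →
  "mixed".
* Problem sizes: 20 slices × 200 frames (4 heartbeat cycles per slice)
  × 128×128 pixels for scenario runs; 64×64 at 2 µm for the gating
  phantom; 256-point time grid and 96 axial stations for kinematics.
  These sizes put every Monte-Carlo check within a few minutes on one
  CPU while keeping the speckle statistics representative.

## 7. What passing the tests shows — and does not

The suite demonstrates that the estimators are correct against analytic
oracles, that the pipeline recovers the phantom's known kinematics,
flux and causal structure at the stated tolerances, and that the two
study conditions are discriminated. It does not demonstrate performance
on real embryonic data: real hearts have non-circular, trabeculated
lumens, bulk motion, attenuation, beat-to-beat variability, and
uncertain Doppler angles; manual segmentation differs from threshold
replicates; and plane placement on a curved tube axis is itself a
choice (a centerline-fitting helper is provided, but the axis remains
user input).
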