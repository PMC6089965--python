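# Methods

This note records the models implemented in `zeptoassay`, their
assumptions, the defaults and the numerical choices, in enough detail to
reproduce or modify any stage.

## Counting statistics

A standard solution of nominal concentration *C* (zM) sampled in volume
*V* (µl) yields a Poisson-distributed molecule count with mean
λ = C·10⁻²¹ · V·10⁻⁶ · N_A. The Avogadro constant is fixed at
6.022×10²³ mol⁻¹; CODATA refinements are invisible at the precision of any
reported quantity.

Two uncertainty sources are propagated per standard, both as one SD:

- **Poisson sampling**: √λ molecules, converted back to molarity
  (√λ / (V·10⁻⁶·N_A) · 10²¹ zM). Its relative size is 1/√λ, so it
  dominates below ~10³ zM in 100 µl.
- **Dilution**: independent multiplicative errors per serial-dilution
  step, relative SD `per_step_cv`, accumulating as c_i·cv·√i after i
  steps. The default cv = 1.5% is a realistic pipetting figure that puts
  the concentrated end of an eleven-decade series at permille-level
  relative error; the dilute end stays Poisson-dominated regardless of cv.

The two combine in quadrature. Dose accumulates across incubations
because one sensing gate is exposed to every standard in turn,
most-dilute-first; the cumulative dose is Σλ_i with SD √(Σλ_i).

Reported molecule counts follow the assay convention: nearest integer with
nearest-integer √λ SD, the SD floored at 1 whenever the count is ≥ 1 (a
single-molecule count is never known to better than one molecule).

Note one deliberate behaviour: at 6 zM in 100 µl the package computes
P(0) = e^(−0.3613) = 69.7%. Published discussions of the same scenario
quote 68.3%; the package always returns the exact Poisson value.

## Transistor transduction

The p-type electrolyte-gated FET is modelled with the saturation square
law I_D = (W/2L)·µC_i·u², u = max(0, |V_G| − |V_T|), appropriate because
the operating |V_D| = 0.4 V equals or exceeds typical overdrives. The
true device physics of a specific sensor will deviate in curve shape; the
model sits behind the single function `drain_current` so it can be swapped
without touching threshold extraction, transconductance or response logic.
Defaults: W = 1280 µm, L = 5 µm, µC_i = 10⁻⁵ A/V², V_T = −0.3 V; gate
sweep −0.1 to −0.7 V in −0.01 V steps at V_D = −0.4 V. Currents are
stored as magnitudes; gate voltages keep their measured negative sign;
responses are positive fractional current decreases.

- **Threshold extraction**: ordinary least squares of √I_D vs V_G
  restricted to the top 50% of the observed overdrive (where the square
  law is cleanest and contact/subthreshold effects smallest); the fitted
  line's root is V_T. Noiseless square-law input is recovered to
  ~10⁻¹⁶ V; at 1% multiplicative noise on the default grid the extractor
  is unbiased with SD ≈ 1.7 mV over 200 seeds. At least 10 points must
  fall in the window.
- **Transconductance**: central finite differences on the measurement
  grid (`numpy.gradient`); the read-out bias is the grid point of maximum
  |dI/dV|. On a pure square law this is the sweep end; real and synthetic
  roll-off curves give an interior maximum.
- **Work function to threshold**: ΔV_T [V] = Δϕ [eV] (unit charge), sign
  preserved — a lowered gate work function shifts V_T more negative on a
  p-type device.
- **Response conversion**: at fixed bias with baseline overdrive u,
  ΔI/I₀ = 1 − (1 − |ΔV_T|/u)², with exact inverse
  |ΔV_T| = u(1 − √(1−R)). A response from a current *increase* is
  reported signed with a warning rather than rejected, since it is
  diagnostic of drift. The read-out bias is frozen from the baseline
  curve for a whole dose series.

## Domain-flipping dose-response model

Assumptions: the monolayer consists of K domains with antibody fractions
a_j > 0, Σa_j = 1, identified with gate-area fractions (domains are defined
by the antibodies they comprise, and the response is proportional to the
area whose work function flips). Sampled ligands bind independently with
capture efficiency η ∈ (0,1]; each binding lands in domain j with
probability a_j; a domain flips irreversibly on its first hit; flipped
state persists across incubations. Hence

R(λ) = r_max · Σ_j a_j (1 − e^(−η λ a_j)), monotone, R(0)=0, R(∞)=r_max.

η defaults to 1: the diffusion estimate below shows that over a 10 min
incubation even single ligands explore the whole 100 µl droplet, and true
capture probability at zeptomolar concentrations is unquantified, so it is
exposed as a parameter rather than buried in a default below 1.

The steepness index R(1)/r_max = Σ a_j(1 − e^(−η a_j)) ≈ η Σ a_j²
quantifies single-molecule-range steepness; it strictly increases under
mean-preserving merging of domains.

**Monte-Carlo oracle.** `simulate_assay` realizes the same process
stochastically (Poisson count → multinomial scatter → flip set), serving
as the independent check of the closed form; the two agree within 3 SE at
10⁵ replicates across random models with up to 50 domains.

**Parametrizations.** (i) N_D equal domains — R = r_max(1 − e^(−ηλ/N_D));
(ii) one dominant fraction a₁ plus N_small equal small domains. A
log-normal fraction generator is provided for synthetic dispersion studies
only. Domain counts are fitted on a log₁₀ scale: they can span many
decades, and linear parametrization with wide bounds defeats the
optimizer's step scaling (this was observed, not hypothesized: linear-
scale fits silently stalled at their initial values). Point estimates and
delta-method standard errors are mapped back to the natural scale.

**Fitting.** Weighted least squares (weights 1/σ²; zero σ floored at the
smallest positive σ) via Levenberg–Marquardt with up to 5 restarts from
perturbed initial values. Confidence intervals use Student-t quantiles
with the residual degrees of freedom — at the ~11-point size of one
calibration curve, normal-quantile Wald intervals are measurably
anticonservative (≈90% empirical coverage at nominal 95%) while t-based
intervals calibrate at 94–97%.

**LOD inversion.** R(λ) = r_lod is solved by bracketing + Brent root
finding at 10⁻⁹ relative tolerance, deliberately parametrization-agnostic
(no closed-form inverse is assumed), then converted to molarity.

**Large-vs-small-domain contrast.** The package expresses the compact vs
defective monolayer comparison as two equal-domain models over the same
5.92×10¹¹ antibodies: domains of 10¹¹ antibodies (N_D ≈ 5.92) vs domains
of 10⁹ (N_D = 592). For equal-domain models the dose reaching any fixed
response level scales exactly with N_D, so the LOD-dose ratio is
592/5.92 ≈ 100 — two orders of magnitude, at any LOD level. A
dominant-fraction-plus-remainder composition (a₁ ≈ 0.17 over small 10⁹
domains) was considered and rejected for this comparison: its LOD-dose
ratio against the all-small model is only ~8–18 because the small domains
contribute at both ends.

## Assay metrics

- **LOD response level**: blank mean + 3·SD. Presets: "pbs"
  (2.0% ± 2.3% → 8.9%) and "serum" (5% ± 5% → 20%). The rule value is
  always returned; a published 11.6% figure for the PBS-like case does
  not follow from the stated noise numbers and is treated as a
  documented discrepancy, not a target.
- **Diffusion feasibility**: 3-D RMSD √(6Dt). The factor 6 (not 2 or 4)
  is the choice consistent with the quoted 0.4 mm for
  D = 4×10⁻¹¹ m²/s over 600 s (√(6Dt) = 0.379 mm).
- **Packing geometry**: antibody density per µm², chains under one
  antibody footprint (footprint/chain-width²: 100 nm² / (0.5 nm)² = 400)
  and total chains per antibody (3.3×10¹⁴/5.92×10¹¹ ≈ 557; the commonly
  quoted round figure is 400–500 — both are reported).
- **Debye length**: full 1:1-electrolyte formula
  √(ε₀εr k_B T / (2 N_A e² I)) with εr = 78.36 at 298.15 K, matching
  0.304/√I nm within 1% over I ∈ [10⁻⁶, 1] M. Ionic strength is always
  an input, never inferred from a buffer name.
- **Run validation**: control drift ≤ 5% accepted, (5%, 8%] accepted
  with a warning, > 8% rejected. The published protocol states the band
  as "5–8%"; it is read as an acceptability band with a warning zone, not
  a single cutoff.

## Trajectory analysis

Input: unwrapped labeled trajectories; per chain a sulfur anchor and a
hydroxyl oxygen (the chain vector is S→O), plus donor–hydrogen–acceptor
triplets for tracked chain pairs. Validation rejects D–H distances
≥ 1.5 Å (not a covalent hydrogen) and triplet spans > 100 Å (wrapped or
broken coordinates). No periodic imaging is applied.

- **H-bond criterion**: donor–acceptor distance ≤ 3.0 Å **and**
  donor–H–acceptor angle (vertex at H) ≥ 150°, both inclusive — the
  standard trajectory-analysis convention for these thresholds.
  Occupancy is the percentage of frames satisfying the criterion.
- **Tilt angle** θ = arccos(v_z/|v|) against the fixed z-axis (surface
  normal / gating-field direction), not the nematic director.
- **Nematic P₂**: fixed-axis ⟨(3cos²θ−1)/2⟩, and the director variant as
  the largest eigenvalue of Q = ⟨(3u⊗u − I)/2⟩; the director variant is
  always ≥ the fixed-axis one and both are reported.
- **Dynamic S**: per chain the *time-averaged* cos²θ is computed first,
  then S = ⟨(3⟨cos²θ_i⟩_t − 1)/2⟩ over chains. This second-Legendre
  time-average form is one of several "dynamic order" definitions in the
  monolayer literature; it is isolated in a single function so an
  alternative can be swapped. Under it, chains stably tilted past the
  magic angle (54.7°) give S < 0, while isotropic frame-to-frame
  wobbling drives S → 0; a single frame is rejected since a time average
  is then undefined.

## Synthetic data

One master seed feeds `numpy.random.SeedSequence([seed, offset])`
substreams with fixed offsets per generator family, so adding draws in one
generator never perturbs another, and identical configurations reproduce
byte-identical artifacts.

- **Transfer curves**: square law on the −0.1..−0.7 V grid times i.i.d.
  lognormal factors exp(N(0, σ)), σ = 1% by default (median-unbiased
  multiplicative instrument noise).
- **Dose datasets**: a simulated gate walks the dilution series
  most-dilute-first with an absorbing flipped-domain state (incremental
  Poisson bindings per incubation, preserving the within-series
  correlation a reused gate induces); responses average 3 replicate gates
  and add Gaussian control noise from the "pbs" (2.0% ± 2.3%) or "serum"
  (5% ± 5%) preset. Default series: stock 6.67×10⁸ zM, 11 decade
  dilutions, cv 1.5%, 100 µl — the calibration design the assay uses.
- **Chain trajectories**: orientations drawn per frame from the axial
  distribution p(θ) ∝ exp(a·cos²θ) (rejection sampling on cosθ; a ≥ 0,
  clamped at 700), chains on a 5 Å grid with 4 Å length; H-bond triplets
  placed in ideal geometry (2.9 Å, 180°) with Bernoulli(occupancy)
  per frame and broken geometry (3.8 Å) otherwise.

What the generators do **not** emulate: instrument drift beyond
multiplicative noise, hysteresis, contact effects, correlated pipetting
errors, real H-bond geometry distributions, collective chain dynamics, or
any force-field physics. Passing tests therefore demonstrate the
correctness and statistical calibration of the analysis pipeline on data
matching its stated noise model — not the physical accuracy of the square
law or of the domain picture on a real device.

## Problem sizes and tolerances

The statistical studies run at: 10⁵ Monte-Carlo replicates × 20 random
models for the oracle check; 200 synthetic calibration curves (12 doses,
2% noise) for CI coverage; 200 seeds for noisy threshold recovery; 10⁴
frame-pairs for occupancy recovery; 10⁴ orientations for isotropic
order-parameter bounds (|P₂|, |S| ≤ 0.03 at that size). These sizes put
every Monte-Carlo bound comfortably past its test tolerance while keeping
the full suite around ten seconds. Root finding uses 10⁻⁹ relative
tolerance; fit restarts are capped at 5; equality-style checks on exact
arithmetic use 10⁻¹²–10⁻⁶ depending on the conditioning of the operation.

## Known limitations

- The square law is a stand-in for the specific device's transfer model;
  curve *shapes* of a real sensor are not reproduced, only the
  V_T-shift phenomenology.
- The domain model ignores binding kinetics, reversibility and spatial
  domain geometry; serum parasitic-capacitance effects are out of scope.
- The domain-size dispersion of a real monolayer is unknown; the
  log-normal generator is for synthetic studies, not inference.
- The dynamic order parameter S follows one specific literature
  convention; trajectories from other tools may define it differently.
- Fit standard errors are curvature-based; for strongly non-linear
  regimes (very few doses, near-saturation designs) profile likelihood
  would be more faithful.
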