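# Methods

## Cylinder hydrodynamics

The sedimenting unit is a rigid circular cylinder: length *l*, height
(diameter) *h*, aspect ratio *q = l/h ≥ 1*. Its sedimentation
coefficient is that of the equal-volume sphere, slowed by the cylinder
frictional ratio:

    s = d_eq² (ρ_F,eff − ρ_S) / (18 η (f/f₀))

* **Equivalent sphere.** Volume equality π h² l / 4 = π d_eq³ / 6 gives
  d_eq = (3 h² l / 2)^{1/3} ≡ (3 h³ q / 2)^{1/3}. A published variant of
  this rearrangement prints the factor as (3 h³ / (2 q²))^{2/3}, which is
  dimensionally a length squared but decreases with length and is
  inconsistent with volume equality; this package implements the
  volume-consistent form, under which *s* grows monotonically with
  length as physically expected.
* **Frictional ratio.** f/f₀ = 1.0304 + 0.0193 k + 0.06229 k² +
  0.00476 k³ + 0.00166 k⁴ + 2.66·10⁻⁶ k⁷ with k = ln q (Hansen's fit to
  numerical solutions for cylinders). Valid for rods; inputs q < 1
  raise rather than extrapolate.
* **Densities.** ρ_F,eff defaults to 1331.6 kg m⁻³ (inverse partial
  specific volume of BLG) × 1.02, the densification of packed β-sheet
  fibril cores relative to the native protein, consumed here as a
  constant. The solvent defaults to water at 20 °C (998.2 kg m⁻³,
  1.002 mPa s); dilute pH-2 HCl is indistinguishable from water at this
  precision. Both are configurable.
* **Hydration.** Enters only through the effective height (AFM
  dried-state height + 0.7 nm for two bound water layers; 4.0 nm →
  4.7 nm) and the effective density. No explicit shell model.
* **Units.** All internal computation is SI; Svedberg (10⁻¹³ s) and nm
  appear only in suffixed interface helpers, avoiding silent 10¹³
  factors.
* **Inversion.** *s(l)* is strictly increasing at fixed *h* (verified on
  grids to q = 10³), so `length_from_s` brackets ln q on [0, ln 10⁶]
  (expanding if needed) and bisects to 10⁻¹² relative tolerance;
  round-trip accuracy is better than 10⁻⁹ relative over l ∈ [50, 2000]
  nm, h ∈ [2, 6] nm. Below the rod limit s(q = 1) no solution exists
  and the call raises.
* **Molar mass.** ρ_F,eff π h² l / 4 × N_A. A 500 nm fibril is ~31 MDa
  with a 5 nm cross-section *radius* and ~7.9 MDa with a 5 nm
  *diameter*; both readings are exposed because the literature figure
  of "31 MDa at 5 nm" is only consistent with the radius reading.

## Weighted distributions

`WeightedDistribution` tabulates a density on a strictly increasing
grid (length in nm or s in S) with an explicit weighting basis. Number
→ mass weighting multiplies by the per-fibril mass ∝ h² l (∝ l at
constant height; the h² cancels on renormalisation). Extinction
weighting equals mass weighting: each fibril is a stack of subunits
contributing equally to the optical signal. Conversions renormalise,
making round trips exact to machine precision.

* **Ingestion.** AFM length records below 50 nm (the image-analysis
  resolution floor) are dropped and counted; survivors are binned into
  64 equal-width bins by default (configurable; `bins=None` keeps exact
  point masses). The binning is this package's choice — the original
  classing equations of the AFM workflow are not public.
* **Fits.** Lognormal and Weibull shapes are least-squares fits to the
  tabulated density (with a free amplitude), the convention when only
  classed densities rather than raw records are available; initial
  values come from weighted moments. Exact tabulated shapes are
  recovered to 10⁻⁶.
* **Axis mapping.** Length ↔ s mapping pushes the grid through the
  forward (or inverse) cylinder model and transforms the density with
  the analytic Jacobian |dl/ds| (central difference of the smooth
  forward model at 10⁻⁶ relative step, accurate to ~10⁻¹⁰), then
  renormalises; the residual discretisation drift is recorded in the
  metadata. Monotonicity makes quantiles equivariant and lets the
  weighting conversion commute with the mapping. s-grid points below
  the rod limit are excluded with the excluded weight reported.
* **Summaries.** Q10/Q50/Q90 by linear interpolation of the cumulative;
  the mode as the grid argmax; the mean as the weighted first moment.
  Two width conventions are reported — (Q90 − Q10)/2 and the weighted
  standard deviation — with the half-span used wherever one number is
  needed. Q50 (median) and the first moment are both reported because
  field usage alternates between them under the name "mean"; in the
  mass-cumulative quantile notation (Q10/Q50/Q90) the central length
  statistic *is* Q50.

## Gravitational-sweep simulator

Each particle follows the overdamped Langevin equation in the
centrifugal field, dr = s ω² r dt + √(2D dt) ξ, by Euler–Maruyama.
Defaults mirror the reference configuration: 30,000 rpm constant,
meniscus 5.9 cm, bottom 7.2 cm, detector 6.9 cm, 7200 s, Δt = 0.5 s,
10⁵ particles per species (noise is generated in float32 for speed;
positions stay float64). Initial positions are drawn ∝ r, the 1D
reduction of a sector-shaped cell, which makes the square-law radial
dilution of plateaus (c ∝ e^{−2sω²t}) emerge from the dynamics; the
meniscus reflects, the bottom absorbs. The drift step is limited to
0.1 mm per step, otherwise the run refuses with guidance. D follows
from (s, f/f₀, ρ_eff) through the equivalent sphere and Stokes drag,
D = k_B T / (3π η d_eq (f/f₀)).

The detector records two channels every 2 s (default): the
abundance-weighted particle count in a 50 µm bin at r_fix, normalised
to its initial expectation (the direct analogue of the optical
signal), and the fraction of particles at or beyond r_fix. The two
carry the same physics — the time derivative of the crossing fraction
is the flux c·v at the detector — but the crossing channel has far
better counting statistics, since every particle contributes exactly
one front passage rather than a brief bin occupancy.

**Recovery.** The arrival-time map s = ln(r_fix/r_m)/(ω² t) converts
the trace to s-space. Differencing a Monte-Carlo trace amplifies
noise, so the default recovery fits the whole trace as a non-negative
superposition of analytic one-species profiles on a 200-point
log-spaced s-grid (non-negative least squares) — the boundary-modelling
strategy of ls-g*-type sedimentation analysis. Profiles include the
square-law dilution and a diffusion-broadened front (erf in time, with
the exact linear-SDE spread), with D(s) derived under an assumed
frictional ratio (default 1.5) and density; for slow species these
parameters only set an irrelevant smear width. A direct "signal-drop"
transform is available for clean or external traces. Material below
the cutoff (default 10 S) is excluded and the result renormalised.

On the three-species control (4/50/100 S, equal extinction weights)
the recovered cumulative distribution reproduces the renormalised
two-step input to ≲ 0.01 sup-distance away from the fronts at 10⁵
particles/species; the grid spacing (~3% relative) and front diffusion
set the resolution immediately around each step, so pointwise
comparisons exclude ±4% windows there. The 4 S material's front would
need ~40,000 s to reach the detector; within 7200 s its bin signal
stays on the dilution plateau to within correlated counting noise
(~2.5% per 12-min window; slow species decorrelate only advectively,
in ~3 min) and its crossing fraction tracks the no-front analytic
curve to < 0.01.

## 2D length × height analysis

Fibril heights are distributed (dominant population 4.0 ± 1.0 nm), not
constant. The joint model multiplies the mass-weighted length
distribution with a normal height density treated as the mass-weighted
height marginal, assuming independence (a direct product of the two
marginals). The height grid spans mean ± 4 sd on 41 points,
truncated at 0.5 nm (a normal admits nonphysical near-zero heights)
and renormalised. Heights are carried as measured (dried) values; the
+0.7 nm water-layer offset is applied when each cell is pushed through
the cylinder model, so the degenerate sd → 0, mean 4.0 nm case
reproduces the 4.7 nm constant-height pipeline. Cells with q < 1 are
dropped (weight reported); per-cell coefficients are classified into
128 linear s-bins up to 1.1× the largest value.

With the AFM-like default fixture the height spread widens the
s-distribution roughly five-fold ((Q90 − Q10)/2 from ~3 S to ~16 S),
adds a tail above the constant-height maximum, and shifts the mode
slightly down — while Q50 stays within half a percent. The first
moment, by contrast, rises by ~3%: the broadened distribution is
right-tailed, so the moment chases the tail while the central value
does not. This is why the central-value constancy claim is assessed on
Q50 (which the quantile notation labels the "mean" length statistic);
the low-s region (< ~15 S) of the broadened distribution combines
short lengths with thin heights never observed experimentally and is
flagged in the output rather than excluded.

## Comminution scaling

Fragment size in top-down stressing follows x = a E_V^(−b). For a
rotor–stator in the turbulent regime (Re = n d_R² ρ/η > 10⁴, Newton
number constant) the power is P = Ne n³ d_R⁵ ρ, so E_V ∝ n³ and
l ∝ n^(−3b), with the stress intensity indexed simply by the rotation
count n = (rpm/60)·t. The fit is ordinary least squares of ln l on
ln n — the standard choice for a relationship that is linear in the
log-log plane; b = −slope/3 with its standard error. The 11,000 rpm / 5 s condition is excluded by default — the
flow pattern is not fully developed within 5 s — and every exclusion
is explicit in the result; no automatic outlier rejection. Rotor
diameter and processed volume are configuration inputs (the dispersing
tool's dimensions are not published); the Re/Ne helpers are
diagnostics only and do not enter the b fit.

## Synthetic data

The fixture generators define the study conditions for all tests:

* AFM lengths: lognormal, shape σ = 0.35 (chosen so ~2000-sample
  extremes fall near the stated 80/810 nm bounds), ln-scale location
  solved so the truncated mean is 395 nm; rejection-sampled, seeded.
* Heights: normal 4.0 ± 1.0 nm, truncated at 0.5 nm.
* s-densities: Weibull (shape 2, scale 30 S, offset 5 S), mode ≈ 26 S,
  inside the 25–42 S band of the stressed-fibril measurements.
* Sweep: the exact three-species configuration above.
* Comminution: l = a n^(−3b) with 5% multiplicative log-normal noise;
  defaults b = 0.2, a = 5.5·10⁴ nm span the observed 100–800 nm modal
  lengths over the 11–24 krpm × 5–90 s grid.

What these fixtures do **not** emulate: fibril flexibility (real
fragments above ~700 nm bend, so cylinder inversion under-resolves the
upper distribution tail), correlated length–height statistics, the
discrete 2/4/6 nm height subpopulations (a continuous normal stands in
for them), optics and instrument noise of the real detector, and
concentration-dependent non-ideality. Passing tests therefore
demonstrate the internal consistency of the model chain and the
recovery machinery at realistic statistics — not the accuracy of the
rigid-cylinder approximation for real, partly flexible fibrils.

## Numerical choices and limitations

* Frictional polynomial applied only for q ≥ 1; no disk branch.
* Root finding: Brent on ln q, tolerance 10⁻¹² relative.
* Problem sizes in the test suite are chosen for single-CPU runs: the
  full 3×10⁵-particle control experiment runs once (~40 s); oracle and
  convergence checks use scaled-down runs (10³–10⁵ particles, shorter
  durations) with fixed seeds.
* Monte-Carlo assertions use noise bounds derived from the counting
  statistics at those sizes (4σ windows); they are diagnostics of
  consistency, not of the underlying physics at higher precision.
* The recovery's NNLS is unregularised; very broad continuous
  distributions recover with grid-limited resolution (~3% in s).
* Neutral buoyancy returns s = 0 with a warning; denser-than-fibril
  solvents give negative s (flotation) in the forward model but are
  rejected by the inverse.
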