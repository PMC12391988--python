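# Methods

This note documents the models implemented in `geldiff`, the assumptions
behind them, the defaults and the numerical choices, and what the synthetic
generators do and do not emulate.

## Slab release model

**Model.** Release of a dissolved or suspended payload from an initially
homogeneous gel slab of thickness *l* with a perfect-sink boundary follows
the classical eigenfunction series

M_t/M_∞ = 1 − Σ_{n≥0} 8/((2n+1)²π²) · exp{−D(2n+1)²π² t/(4l²)}.

The full measured thickness (default 1.26 mm) enters the 4l² denominator
directly. Physically this is one-sided release from a slab sealed at its
base — the geometry of a gel cured at the bottom of a cuvette with buffer
added on top. The sink condition assumes the supernatant volume is large
enough that the released payload never builds up a back-concentration.

**Mobile fraction.** Payload particles larger than the network mesh are
obstructed; only a mobile fraction f_mob ∈ [0, 1] is ever released by
diffusion. The observed profile is f_mob · M_t/M_∞ and plateaus at f_mob.
The two parameters are separately identifiable because f_mob sets the
plateau while D sets the time scale of approach to it.

**Numerics.** The series is truncated adaptively: summation stops when the
next term falls below `tol` (default 1e-10) times the partial sum, with a
hard cap of 10 000 terms. For Dt/l² < 1e-4, where convergence is slow, the
code switches to the early-time law 2·√(Dt/(πl²)), which is accurate to
~1e-9 there. Agreement with an independent Crank–Nicolson solution of the
slab PDE is better than 1e-4 absolute over Dt/l² ∈ [1e-3, 10] (tested).

**Fitting.** `fit_release` minimises squared residuals over all replicate
points pooled (not averaged first, so replicate scatter stays in the
residuals). D is log-parameterised and f_mob logit-parameterised to enforce
the physical ranges without constrained optimisation. Five deterministic
starts are used — D seeded from the early-time square-root law at the first
positive sample and scaled by {0.04, 0.2, 1, 5, 25}; f_mob from the mean
value at the last time point — and the lowest-cost solution wins, ties
broken by the smallest D. Standard errors come from the Gauss–Newton
quadratic approximation at the optimum, mapped back to (D, f_mob) by the
delta method. An all-zero curve returns f_mob = 0 with
`d_unidentifiable=True`; a mean trend that decreases by more than
max(0.02, 2·residual sd) between successive sampling times sets
`non_monotone_trend` (cumulative release cannot decrease; such data usually
indicate a pipetting or calibration problem).

**Calibration.** Raw supernatant fluorescence is converted to fraction
released through an ordinary-least-squares line fitted to standards
(`amount, signal`), with optional blank subtraction:
fraction = (signal − blank − intercept)/slope/loaded_amount. Negative
computed fractions are clipped at zero with a recorded count; values below
−0.02 before clipping raise a flag since they suggest a calibration offset
rather than noise.

## Network-diffusion models

**Mesh relation.** For a random network of straight cylindrical fibers of
radius R_f at volume fraction φ, the mesh radius — the largest sphere
radius that on average fits into the network without touching a fiber — is
r̄ = R_f·√(π/φ). This relation is typeset ambiguously in parts of the
hydrogel literature; the form used here is the unique power law in
(R_f, φ) consistent with the standard numerical values for dilute networks
(14 nm at R_f = 1 nm and 140 nm at R_f = 10 nm for φ = 0.016), and it is
documented prominently in `gel_network`. R_f is never fitted: it is a
structural hypothesis (1 nm for single collagen triple helices, 10 nm for
fibril bundles) under which the rest of the analysis is conditioned.

**Volume fraction.** φ = (w/ρ_p)/(w/ρ_p + (1−w)/ρ_s) from the polymer mass
fraction w assuming additive volumes; defaults ρ_p = 1.3 g/mL (collagen)
and ρ_s = 0.997 g/mL (water). The gel studied has w = 0.0206 → φ = 0.016.

**Obstruction and hindered diffusion.** Ogston–Amsden gives
D_g/D_0 = exp{−(π/4)((R_h+R_f)/(r̄+R_f))²}: purely steric exclusion,
rigid fibers, spherical probe. Clague–Phillips adds fiber hydrodynamics:
D_g/D_0 = (1+2α/3)⁻¹·exp{−π·φ^(0.174·ln(59.6·R_f/R_s))} with
α = φ((R_s+R_f)/R_f)²; the pre-exponential factor is the Tsai–Strieder
obstruction result and the exponential a regression to hydrodynamic
simulations, valid for R_s < 59.6·R_f. Outside that range the code emits a
`RuntimeWarning` rather than failing, since the pre-exponential factor
remains meaningful. The solute radius R_s of the hindered-diffusion model
is identified with the hydrodynamic radius R_h throughout — both are
defined operationally through the free-solution diffusivity.

**Free diffusivity.** Stokes–Einstein D_0 = k_B·T/(6πηR_h) with
k_B = 1.380649×10⁻²³ J/K (CODATA), default T = 307 K and
η = 7.34×10⁻⁴ N·s/m² (water at that temperature). All computation is SI
internally; interfaces use nm and μm²/s, with every conversion centralised
in `geldiff.units`.

**Inversion.** `invert_radius` solves D_g(R_h) = target on the composite
curve, which is strictly decreasing in R_h (both factors decrease). The
root is bracketed on a 512-point log-spaced scan of [0.1, 10 000] nm and
polished by bisection to relative tolerance 1e-9 — fully deterministic. A
target above the curve's range raises an explicit out-of-range error.

**Mesh estimation.** `estimate_mesh_from_probes` fits r̄ (single free
parameter, log-parameterised) to a probe panel by least squares in
D_g/D_0 ratio space rather than raw D_g, so probes of very different size
— whose absolute diffusivities span an order of magnitude — carry equal
weight; ratios are also the quantity the theory actually predicts. D_0 is
taken from the probe record when measured, otherwise from Stokes–Einstein.
The initial guess is the median of per-probe closed-form inversions. An
RMS ratio residual above 0.05 sets `poor_fit` (a ratio is order 1, so 0.05
means the model misses the panel by ≈5 percentage points on average).

## FRAP model

**Model.** The recovery implemented is the ROI-averaged closed form for an
instantaneous, uniform bleach of depth K in an L_x × L_y rectangle embedded
in an infinite 2-D medium with pure diffusion:

F(t) = 1 − K·g(t; L_x)·g(t; L_y),
g(t; L) = erf(w) + (exp(−w²) − 1)/(w√π), w = L/(2√(Dt)).

Derivation: the 1-D top-hat bleach profile evolves under the heat kernel
into a difference of error functions; averaging it back over the ROI gives
g, the fraction of the initial 1-D deficit still inside the ROI. The 2-D
propagator factorises, so the rectangular deficit fraction is the product
of the two axis factors. Limits g(0) = 1 and g(∞) = 0 give F(0) = 1 − K and
full recovery. The closed form was validated against a 2-D Crank–Nicolson
(ADI) finite-difference solution on a padded domain: RMS deviation ≈ 0.4%
of K over 1%–95% recovery (tested at D = 10, 64.6 and 232 μm²/s).

**Assumptions.** No bleaching during acquisition, no reaction/binding term,
no immobile fraction (immobility is the tracking module's job), intensities
normalized to the prebleach ROI mean, and a medium much larger than the
ROI (infinite-reservoir recovery to 1). Default ROI 100 × 100 μm and ~25%
bleach depth match the measurement protocol the package targets.

**Fitting.** K is initialised from the first post-bleach frame and refined
in the fit unless `fix_bleach_depth` is set; D is log-parameterised, with
the start estimated from the observed half-recovery time (g² = 1/2 at
w ≈ 1.11) and three decade-spaced multi-starts. A curve whose total
recovery is below 3× the noise scale is returned with
`d_unidentifiable=True` — the immobile-probe case. Intensities above
1 + 3·noise set `above_unity_flag` (normalization problem).

## Particle tracking

`track_stats` computes, per track: the maximum Euclidean distance from the
first position (the headline mobility statistic — model-free, robust to
track length), the contour path length, and the time-averaged MSD using all
overlapping same-lag pairs; lag times are multiples of the median frame
interval. For free 2-D Brownian motion the lag-1 MSD expectation is 4DΔt,
which the simulation tests verify to within 3 standard errors.

`population_summary` histograms the max distances (Freedman–Diaconis
default bin width, configurable since reporting conventions vary) and
optionally fits a two-component Gaussian mixture on **log** distances —
distances are positive and right-skewed, and on the log scale the mobile
and immobilized populations are roughly symmetric clouds. The EM uses a
deterministic seeded k-means++-style initialisation, a variance floor of
1e-12, and runs until the log-likelihood changes by < 1e-10 (the trace is
recorded and is nondecreasing, as EM guarantees). Components are reported
in increasing order of mean. The `separated` flag requires (i) the
component means to differ by at least one pooled within-component standard
deviation and (ii) BIC to prefer two components over a single Gaussian.
The BIC gate is essential: a 2-component EM fit to a single homogeneous
cloud routinely converges to overlapping or small-spike splits whose mean
difference alone exceeds the pooled sd, and the model-selection criterion
reliably rejects these (measured false-separation rate ≈2% on single
log-normal clouds, against 100% detection for genuinely bimodal data).
Zero max-distances cannot enter the log-scale mixture; they are counted and
reported separately. Pixel-to-μm conversion is explicit: tables with pixel
coordinates require a `pixel_size_um`.

## Synthetic generators

Every generator is a pure function of its config (seed mandatory); outputs
are byte-identical across reruns and ship a ground-truth JSON sidecar.

* **Release** (defaults): sampling days 0, 1, 2, 10, 14, 20, 30, 35;
  D = 2.5 μm²/s, f_mob = 0.36, l = 1.26 mm; additive Gaussian noise,
  sd 0.05 in fraction units (≈±5 percentage points of replicate scatter);
  4 replicates; clipped at 0 with the clip count recorded. Additive rather
  than multiplicative noise because the replicate scatter of a plate-reader
  release assay is roughly constant in absolute fraction units.
* **FRAP**: 100 × 100 μm ROI, K = 0.25, default D = 64.6 μm²/s, additive
  intensity noise sd 0.01, uniform 0–240 s grid (121 frames) — long enough
  that even the slowest probe of interest (36.7 μm²/s) exceeds 90%
  recovery.
* **Tracks**: 200 tracks, 50 frames at Δt = 0.5 s; 40% mobile
  (free Brownian, D = 1 μm²/s — the scale expected for ~100 nm particles
  in an aqueous pocket), 60% immobilized (Brownian motion confined to a
  reflecting disk of radius 0.3 μm, mimicking a network cage); Gaussian
  localization noise, sd 0.03 μm, added to reported positions only. The
  40/60 split reflects a release experiment in which roughly a third of the
  payload escapes.
* **Probes**: radii 0.7, 3.0, 7.95 nm (the 4, 70 and 500 kDa dextran
  panel), D_g from the chosen network model with multiplicative log-normal
  noise (cv 0.05) so noisy values stay positive and noiseless output equals
  the model exactly.

**What the generators do not emulate:** photobleaching during FRAP
acquisition, detector shot noise structure, tracking linkage errors and
track-length censoring, vesicle polydispersity (a single effective D
stands in for the released subpopulation), gel swelling or degradation
during release, and any spatial heterogeneity of the network. Passing the
recovery tests therefore shows the estimators are correct and well
calibrated under the stated noise models — not that real data meet those
models.

## Problem sizes and calibrated tolerances

Simulation-based tests use: 100 seeds for release parameter recovery
(median relative error ≤25% on D, ≤10% on f_mob at the default design —
tolerances calibrated by simulation before freezing), 50 seeds for FRAP
(median relative error on D ≤5% at 1% noise), 200 seeds for mesh recovery
(median |r̄ error| ≤15% at 5% probe noise), 200–400 tracks for MSD and
mixture checks, and 1-D/2-D finite-difference oracle grids of 2000 nodes
and 599² nodes respectively. These sizes make the full suite complete in
well under a minute per stage while leaving the statistical assertions
comfortably powered.

## Known limitations

* The slab model ignores swelling, erosion and enzymatic degradation; it
  describes only the diffusive phase of release.
* The obstruction models assume rigid, straight, randomly oriented fibers
  and a dilute network; they degrade for φ ≳ 0.1 and for probes
  approaching the Clague–Phillips validity bound R_s < 59.6·R_f.
* The FRAP model's instantaneous-bleach assumption biases D upward when
  the bleach duration is comparable to the recovery half-time.
* The mixture decomposition assumes log-normal subpopulations; heavy
  tails from tracking errors can inflate the minor component's weight.
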