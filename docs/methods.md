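# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `myoxi`, in the spirit of a modelling appendix: what
is computed, under which assumptions, and what the validation does and
does not establish.

## Section geometry and morphometry

A muscle section is a region-of-interest (ROI) polygon, fibre outline
polygons with type labels {I, IIa, IIb/IIx} and capillary points, all
in µm (origin bottom-left), serialised as a GeoJSON FeatureCollection.
Fibre cross-sectional areas use the shoelace formula; composition is
reported both numerically (count share) and areally (area share).

Capillary domains are unbounded Euclidean Voronoi cells clipped to the
ROI, with no maximum-diffusion-distance cap.  The local
capillary-to-fibre ratio of fibre *i* is the sum over capillaries of
the area fraction of each capillary's domain overlapping that fibre;
dividing by the fibre's area gives the local capillary density.  This
domain-overlap definition has two structural properties the tests
exploit: domain areas sum exactly to the ROI area (so mean CDA × CD ≡ 1
in consistent units), and on gap-free tilings Σᵢ LCFRᵢ equals the
capillary count.  Interstitial (non-fibre) space contributes to domain
area but to no fibre's LCFR.

The counting frame follows the Gundersen convention: fibres touching
the left/bottom (inclusion) edges are kept, fibres touching the
right/top (exclusion) edges are rejected, capillaries are kept when
inside the frame.  CDA includes ROI-border-clipped domains by default;
a flag excludes them, since their true extent is censored.

Units: CSA and CDA in µm²; CD and LCD in mm⁻² (×10⁶ conversion).

## Tissue PO₂ model

Steady-state oxygen transport over the section cross-section:

    ∇·[(D_O₂·α + D_Mb·C_Mb·S′(P)) ∇P] = q·M₀·P/(P + P_crit)   in fibres
    ∇·[ D_O₂·α ∇P] = 0                                        elsewhere

with S(P) = P/(P + P50_Mb).  Capillaries are Dirichlet discs of radius
r_cap at fixed wall PO₂; the ROI boundary is zero-flux.  Extracellular
space diffuses but neither consumes oxygen nor carries myoglobin.
Consumption is uniform across fibre types.

Parameters (defaults, overridable):

| parameter | default | unit | note |
|---|---|---|---|
| M₀ (max consumption) | 15.7×10⁻⁵ | ml O₂ ml⁻¹ s⁻¹ | rat muscle estimate |
| C_Mb (myoglobin capacity) | 10.2×10⁻³ | ml O₂ ml⁻¹ | |
| α (O₂ solubility) | 3.89×10⁻⁵ | ml O₂ ml⁻¹ mmHg⁻¹ | |
| D_Mb | 1.73×10⁻⁷ | cm² s⁻¹ | myoglobin diffusivity |
| D_O₂ | 2.41×10⁻⁵ | cm² s⁻¹ | free-O₂ diffusivity |
| P50_Mb | 5.3 | mmHg | myoglobin half-saturation |
| P_crit | 0.5 | mmHg | Michaelis constant |
| r_cap | 1.8–2.5×10⁻⁴ | cm | capillary radius |
| P_cap | 30 | mmHg | capillary-wall PO₂ |
| q | rest 0.1, max 1.0 | — | demand scale |

The capillary-wall PO₂ and the resting demand fraction are modelling
choices, not measured quantities: absolute PO₂ values therefore carry
an offset uncertainty of a few mmHg, and the model's intended outputs
are *relative* contrasts (between fibre types, demand levels or
groups).  A dedicated robustness test confirms the sign of a
between-section contrast in mean PO₂ is stable under ±10% perturbation
of the myoglobin parameters.  The value 1.73×10⁻⁷ cm² s⁻¹ is used as
the myoglobin diffusivity; free O₂ in muscle diffuses two orders of
magnitude faster, which the separate D_O₂ default reflects.

### Discretisation

Uniform finite differences (5-point stencil) at grid spacing `grid_h`
(default 1 µm; the solver refuses grids coarser than r_cap), with
harmonic face conductivities at fibre/extracellular interfaces.  The
Michaelis–Menten sink is linearised per Picard iteration as
q·M₀·P/(P_prev + P_crit), which keeps the system an M-matrix, so
iterates obey the discrete maximum principle 0 ≤ P ≤ P_cap.  Iteration
stops when the relative sup-norm change falls below `tol` (default
1e-8); non-convergence within `max_iter` raises with the residual.

Capillary-boundary faces use a radial log-corrected (Peaceman-type)
coupling: the steady radial resistance between the capillary circle
and a node at radius r is ln(r/r_cap)/k per subtended radian, and each
capillary's staircase of boundary faces is normalised to the arc of
its circle lying inside the ROI.  This removes the staircase's
effective-radius bias (the dominant error of naive pinned-disc
Dirichlet treatment, which is log-amplified across the whole domain)
while keeping the coupling inside the matrix, so the discrete
consumption/influx balance holds to machine precision.  Against the
closed-form Krogh cylinder (zero-order consumption, no myoglobin, one
central capillary in a 200×200 µm disc) the solution is within 1% of
the analytic profile at all radii on a 1 µm grid, and the mean tissue
PO₂ changes by <0.5% when the grid is halved.

The Krogh reference implemented is

P(r) = P_cap + (M/4K)(r² − r_cap²) − (M·R_t²/2K)·ln(r/r_cap),  K = D_O₂·α,

which satisfies ∇·(K∇P) = M (consumption as a sink), P(r_cap) = P_cap,
P′(R_t) = 0 and the wall flux balance
2π·r_cap·K·P′(r_cap) = −M·π(R_t² − r_cap²).

## Contractile mechanics

*Twitch kinetics.*  Baseline is the pre-stimulus mean.  The trace is
lightly smoothed (Savitzky–Golay, ~3 ms window, order 2) before peak
and half-relaxation detection — at 10 kHz sampling this leaves
noiseless metrics unchanged while keeping the bias of both metrics
under 1% at 2% amplitude noise; the peak amplitude itself is read from
the raw trace at the smoothed peak index to avoid flattening sharp
apices.  HRT is measured to 50% of the amplitude above baseline (the
standard convention), with linear interpolation between samples.

*Specific force.*  CSA = mass/(L₀ × 1.06 g cm⁻³); gram-force converts
to newtons via 9.80665×10⁻³.

*Shortening velocity.*  Least-squares slope over the "linear section"
of an after-loaded transient: starting 10 ms after the release, the
window grows while the local (2 ms) slope stays within 5% of its
initial value; a window shorter than 5 ms is an error.  Shortening is
positive, in L₀/s.

*Force–velocity.*  The hyperbolic-linear form
V(f) = b(1−f)/(f+a) + c(1−f) (f = F/P₀) is fitted by bounded least
squares from a Hill prefit; constraining c = 0 recovers the pure Hill
fit.  Vmax = V(0); Ẇmax is the maximum of f·V(f) located on a dense
grid with parabolic refinement; the power ratio Ẇmax/(P₀·Vmax) is the
curvature index (exactly 0.25 for a linear relation, smaller for more
curved ones).  Results expose W/kg when P₀, L₀ and mass are given.

*Work loops.*  Net work is ∮F dL per cycle (shortening work positive),
trapezoid-integrated with periodic closure of each loop; when several
cycles are present the first is discarded as a transient and the rest
averaged.  Net power = net work × cycle frequency / mass.

*Fatigue.*  Twitch peaks are local maxima above 5× the baseline noise
SD with a 5 ms refractory window; the fatigue index is 100× the mean
of the last five peaks over the mean of five peaks around the maximum.
The index is reported in percent (values near 50 mean tension halved);
some reports print the equivalent fraction with a % sign — the ×100
convention is used consistently here.

*Preparation decline.*  Reference contractions define a piecewise-linear
fractional decline (relative to the first reference); trial values are
divided by the interpolated fraction at their time.

## Haemodynamics and disarray

Resting flow is the mean over a window (default 30 s) immediately
before stimulation onset; end-stimulation flow the mean over the final
window of stimulation.  Conductance divides each window's flow by its
mean arterial pressure; the hyperaemic scope is the end/rest
conductance ratio (the source figures plot a unitless scope without a
formula; this ratio is the definition adopted).  The specific flow
delta divides by a single muscle's wet mass by default.

The disarray index is the R² of an ordinary least-squares 5th-order
polynomial fit of helix angle against fractional transmural distance
(0 = endocardium, 1 = epicardium); at least 7 points are required, and
R² is invariant to affine rescaling of the angles.

## Synthetic-data generators

All generators take explicit integer seeds (no global random state)
and are byte-reproducible.  What they emulate — and what they do not:

*Sections.*  Poisson seed points with 5 Lloyd iterations yield convex,
fibre-like cells tiling a square ROI.  Per-fibre target areas are
drawn lognormally around the per-type mean FCSA (CV default 0.25,
typical of adult rat muscle), renormalised to the exact per-type mean,
and greedily matched (largest target to largest cell) before shrinking
each cell toward its centroid — shrink-only, so the requested total
fibre area must fit in the ROI.  The unshrunk tessellation (option
`scale_to_fcsa=False`) is gap-free and feeds the conservation tests.
Capillaries occupy tessellation junction vertices first (the
anatomical position between fibres), then shared-edge midpoints,
subsampled by seed to hit the target C:F count exactly.  ROI sides in
the study registries allow ~35% interstitial headroom.  Not emulated:
staining, pixel noise, non-convex fibre outlines, spatially correlated
capillary loss — so passing morphometry tests demonstrates correctness
of the measurement code, not robustness to segmentation error.

*Twitches.*  Difference of exponentials with (τ_rise, τ_decay) solved
numerically from the requested time-to-peak and half-relaxation time;
amplitude defaults to the twitch:tetanus ratio times tetanic force.
Noise is i.i.d. Gaussian per sample — the simplest model under which
the recovery tests are meaningful; real force noise is coloured.

*Isotonic transients.*  Constant length until release, an 8 ms
quadratic velocity ramp, then exact linear shortening at the Hill
velocity V(F) = Vmax·c(1−f)/(f+c) for load fraction f and curvature
c = a/P₀.

*Work loops.*  Sinusoidal length (strain default 0.065 L₀), force from
first-order activation (τ_act 25 ms, τ_deact 35 ms) gated by the
per-cycle stimulation window and shaped by a Hill force–velocity
factor; this reproduces an intermediate optimum cycle frequency
(≈5 Hz under the diaphragm conditions).  Alternative force laws
("elastic", "shortening_step", or a callable) exist for closed-form
energetics checks.

*Flow recordings.*  Exponential rise from resting to plateau flow
during stimulation (τ default 5 s), symmetric decay after, constant
mean arterial pressure.  The study registries set the control/HFpEF
resting flows and muscle-specific deltas to the printed group means;
the plateau is resting + specific-delta × muscle mass.  Note the
printed hyperaemic *scope* (a conductance ratio) is not jointly
consistent with the printed resting flow and specific delta under
constant pressure — the generators follow the flow quantities and
report whatever scope they imply.

*Helix profiles.*  5th-order polynomial of fractional depth plus
Gaussian angular noise; at least 7 points.

## Pipeline and statistics

`run_pipeline` validates the config before any computation, derives
every replicate seed deterministically from the top-level seed, and
writes full-precision CSVs plus a rendered markdown table (percent
differences to the nearest integer, ratios to 2 decimals — rounding
happens only at rendering).  Group comparisons use Welch's unequal-
variance t-test by default, with a pooled-variance flag; with the
noiseless default mechanics profiles some metrics have zero replicate
variance and their p-values are degenerate by construction.  Percent
differences are ratios of group means, signed relative to the control
group.

## Problem sizes and known limitations

The test suite and acceptance script run on 16–155-fibre sections,
2 µm PO₂ grids for full sections and a 1 µm grid for the Krogh disc —
sizes chosen so a complete validation pass takes a few minutes on one
CPU; all routines accept larger inputs unchanged.  Limitations: the
PO₂ model is 2-D and steady-state with no haemodynamic coupling and no
per-type metabolic differences by default; absolute PO₂ levels depend
on an assumed capillary-wall PO₂; the morphometry assumes polygons are
already segmented; repeated-measures statistics for whole curves are
out of scope (curves are compared descriptively).
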