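# Methods

## Scope and model

`hemoflow` models steady blood flow through the microvasculature of a rat
retina at the scale of a confocal field of view (2.3 mm × 2.3 mm × 0.06 mm,
75 axial slices), from image to wall shear stress. The chain is:

1. a synthetic vascular generator producing ground-truth networks and
   confocal-like image stacks,
2. classical 3-D vessel segmentation scored by the Dice coefficient,
3. centerline extraction from binary masks into a vessel graph,
4. a reduced-order network flow solver with Carreau–Yasuda (CY)
   shear-thinning rheology,
5. a study layer: arteriole/venule boundary-pressure scenarios and
   volume-targeted capillary dropout.

The flow model is one-dimensional: every vessel segment is a rigid straight
cylinder in steady, fully developed flow, and nodal mass conservation
(Kirchhoff) with Dirichlet pressures at tagged terminals closes the system.
Inertia is neglected — segment Reynolds numbers are far below unity at
capillary scale and are reported as a diagnostic. Within this model the
per-segment momentum balance is exact: τ_w = |Δp|·R/(2L), so wall shear
stress is an algebraic consequence of the converged pressure field. What the
model deliberately omits relative to a 3-D finite-volume solution: junction
losses, non-circular lumens, secondary flows and recirculation at
bifurcations, wall compliance, and pulsatility.

## Rheology

The constitutive law is the five-parameter Carreau–Yasuda model

    η(γ̇) = η∞ + (η0 − η∞)·[1 + (λγ̇)^a]^((n−1)/a)

with widely used whole-blood constants as defaults: η0 = 0.16 Pa·s,
η∞ = 0.0035 Pa·s, λ = 8.2 s, a = 0.64, n = 0.2128, density ρ = 1050 kg/m³.
All are overridable; density enters only the Reynolds diagnostic.

Tube flow under a pressure drop uses the Weissenberg–Rabinowitsch–Mooney
relation, Q = (πR³/τ_w³)·∫₀^{τ_w} τ²γ̇(τ) dτ, where γ̇(τ) inverts the
strictly increasing stress law by Brent bracketing (relative tolerance
1e-10). The public `tube_flow` evaluates the integral by adaptive quadrature
(relative tolerance 1e-8); the network solver uses a precomputed log–log
table of the same integral (8193-point cumulative Simpson over wall stresses
1e-8…1e7 Pa, Hagen–Poiseuille closed form below the grid), which agrees with
the adaptive quadrature to ~1e-6 relative and is exercised against it in the
tests. Least-squares CY fitting minimizes log-viscosity residuals (so both
plateaus carry equal weight) with positivity enforced through log-space
parameters; a fit with η0/η∞ < 1.05 is flagged degenerate because λ, a, n
are then unidentifiable.

## Network solver

Picard iteration: conductances start from Hagen–Poiseuille at η0; each sweep
solves the sparse reduced nodal system for interior pressures, recomputes
segment flows from the tabulated tube-flow law at the current pressure
drops, and blends implied conductances with under-relaxation 0.5.
Convergence is declared when the largest change in any segment flow,
relative to the largest flow magnitude, falls below 1e-6 (at most 200
sweeps; failure raises an error carrying the residual history). The reported
flows come from the final linear solve, so interior mass conservation holds
to linear-solver precision; the constitutive consistency τ_w = η(γ̇_w)·γ̇_w
holds to the inversion tolerance. For a Newtonian fluid the first sweep is
exact and the scheme terminates after a confirming sweep.

Boundary presets (mmHg): baseline 100/10, elevated arteriole 130/10 and
150/10, elevated venule 100/30 and 100/50, converted at 133.322 Pa/mmHg.

One caution on a tempting invariant: segment-wise bracketing of the CY
solution by the η0- and η∞-Newtonian solutions is *not* a theorem on
heterogeneous networks — flow-split redistribution produces relative
violations at the 1e-4 level. Bracketing of the total inflow is exact and
tested strictly; per-segment bracketing is tested with a small slack.

## Synthetic vasculature

The generator emulates a field of view centered on the optic disc. Three
arteriole and three venule trees alternate radially; each trunk (28 µm
tapering to 13 µm) sheds azimuthal terminal branches ("comb teeth", ~5.8 µm)
that run along circles of nearly constant radius into the gaps between
trunks. Venule combs are staggered half a trunk step (50 µm) radially, so
arteriole and venule teeth interdigitate, and short capillary rungs
(4–7 µm lumen, never above 7 µm) bridge facing teeth — the ladder-like
terminal microvascular unit of textbook microcirculation. An optional
jittered-lattice capillary mesh can be woven through the plexus
(`mesh_keep_prob`; off by default).

This architecture is a deliberate choice with a hemodynamic justification.
Under fixed boundary pressures, the response of surviving-capillary wall
shear stress to random capillary removal depends on where the hydraulic
resistance sits. If the removable capillaries form a diffuse mesh, removing
30% of their volume cuts the bed conductivity roughly like lattice bond
dilution, strands survivors at near-zero shear, and the surviving-bed mean
*falls*. Measured increases of both WSS and velocity under rarefaction
require the removable vessels to be parallel single-segment conduits whose
series resistance lives in elements *shared* by many of them (the teeth and
trunks): then total flow barely drops and each surviving rung carries more.
The comb-and-rung layout realises exactly that — and it is also how terminal
arterioles, capillary rungs and postcapillary venules are actually arranged.

Vessel calibres are then set by shear-driven structural adaptation under
baseline perfusion, the standard stable form of diameter control in
microvascular modelling, implemented dilate-only:

* vessels whose wall shear exceeds a set point (16 Pa) dilate toward it
  (τ_w ∝ Q/R³ at fixed flow), clipped to per-class calibre ranges
  (capillaries 4–7 µm, order-2 vessels 5.4–6.0 µm, order-1 13–28 µm);
* capillaries already at maximum calibre and still above a 20 Pa ceiling
  split into two parallel lumens (intussusceptive angiogenesis);
* capillaries chronically below 2 Pa regress and are removed (never severing
  the last perfusion path).

Narrowing is deliberately absent: in a pressure-driven bed a cold vessel is
Δp-driven (τ_w ∝ R), so narrowing it only starves it further — an unstable
feedback we observed directly. Six remodelling passes run in three phases
with regression between them, always ending on remodelling.

This is a calibration in the stated sense: the calibre ranges and set points
were chosen so that baseline capillary-network wall shear stresses land in
the physiological 0–20 Pa window with a mean near 14 Pa, and they are fixed
defaults of `GeneratorParams`, not tuned per run. Every generated structure
is a pure function of (parameters, seed).

Rendering: voxel centers lie at origin + index·spacing; a voxel is vessel
iff its center is within a segment's radius. The confocal model is
blur(label·signal) + background, Poisson shot noise on the expected
intensity plus Gaussian read noise (σ = 8 counts by default, signal 150 over
background 20, PSF σ = 2 µm) — the standard confocal approximation. Scanner
lateral resolution and intensity statistics of the real acquisitions are not
published, so these defaults are plausible-by-construction, not measured.

What passing tests on these phantoms do **not** show about real data:
real capillary networks are denser and more tortuous, have hematocrit-
dependent effective viscosity (no Fåhræus–Lindqvist correction is applied),
imaging artifacts beyond blur+noise (bleaching, depth attenuation, motion)
are absent, and the ground-truth labels are perfect by construction.

## Segmentation

Anisotropy-aware Gaussian smoothing (scales in µm divided by the per-axis
voxel pitch), automatic thresholding, and removal of connected components
below 64 voxels. The default threshold is the FWHM rule — background level
(volume median) plus 40% of the background-to-peak dynamic range — which
recovers the boundary of a blur-broadened binary object and is invariant to
additive intensity shifts. Otsu and fixed thresholds are selectable. A
multiscale Frangi-type Hessian vesselness gate (per-axis Gaussian-derivative
sigmas) is implemented and available, but disabled by default: at 2.25 µm
lateral pitch the capillaries span only one to two voxels, below the scale
where tube filters discriminate, and the FWHM rule measurably dominates.
Dice against ground truth: ≈0.95 at the default noise level on crop-scale
phantoms, 1.0 in the no-blur no-noise limit. Dice of two empty masks is
defined as 1 (perfect-agreement convention). Note the published 0.7 Dice
figure refers to real rat data against expert labels; the synthetic score is
an analogue, not a replication.

## Extraction

`skimage` 3-D thinning produces the centerline; 26-connectivity chains
between terminals (degree 1) and junctions (degree ≥ 3) become polyline
segments, simplified by Ramer–Douglas–Peucker at half-voxel tolerance (each
emitted segment is straight between its endpoints, as the network container
requires). Radius is the mean Euclidean distance-transform value along the
chain — the mean, not the maximum, to resist junction inflation. Two
artifact corrections, both standard: terminal spurs shorter than twice the
local radius are pruned, and junction clusters joined by a chain shorter
than max(2·radius, 20 µm) are merged into one bifurcation (a thick vessel's
junction thins into several adjacent triads). On a reduced-scale phantom the
round trip recovers the ground-truth junction count exactly; the 15%
round-trip tolerance in the tests is an engineering margin, not a measured
limit.

## Experiments

Dropout removes whole capillary segments at random (seeded) until the
removed share of baseline capillary volume is within ±0.02 of the target;
a removal that would sever every inlet-to-outlet path is skipped, and
capillaries stranded from all roots by a removal count toward the removed
volume (they are unperfused). Surviving segment identities are stable.

Radial sections: segments are binned by in-plane midpoint distance from the
field center (the optic-disc proxy) into three equal-width bands spanning
the network's radial extent, section 1 innermost.

Averaging domain: summary wall-shear statistics (baseline mean and maximum,
section means, dropout and pressure-scenario deltas) are computed over the
capillary network — the capillary-class segments — because that is the
domain the reported retinal values refer to, and because the feeding
arterioles and draining venules respond with the *opposite* sign to
capillary rarefaction (they carry less flow when the bed resistance rises).
`ExperimentResult` reports both all-segment and capillary-bed statistics.
"Affected areas" after dropout are the surviving segments sharing a node
with a removed segment (1-hop neighbors); percent changes there are reported
only for segments whose baseline shear exceeds 1% of the network mean, since
a ratio over a near-zero baseline is noise.

## Numerical choices and degenerate inputs

* Picard: under-relaxation 0.5, tolerance 1e-6, max 200 sweeps, η0
  initialization.
* Convergence metric: max|ΔQ| / max|Q| (not per-segment relative change,
  which is ill-posed for the zero-flow dead ends dropout creates).
* Position-only nodes carry no equation and are excluded from the solve;
  nodes unreachable from every boundary terminal are an error naming the
  node.
* Discretization-independence and velocity comparisons use a flow floor
  (1% of mean speed): relative change on a numerically zero velocity is
  meaningless.
* Zero-length segments, non-binary labels, non-positive spacings, missing
  spacing sidecars, and untagged roots are all rejected loudly.

## Problem sizes

The default network has ≈430 segments (≈150 capillary rungs after
adaptation and regression); solves converge in under ten Picard sweeps in
tens of milliseconds. Segmentation checks run on a central
576 × 576 × 60 µm crop (256 × 256 × 75 voxels) of the full-scale phantom;
extraction round-trip checks use a miniature 800 × 800 × 60 µm
configuration. These sizes make the full pipeline, including the scenario
suite over five dropout seeds, run end-to-end in seconds.

## Known limitations

* The dropout response of mean capillary WSS saturates near +28% at 30%
  volume loss (five-seed average), just under the +30% reported for the
  reference experiment; the same physics caps the 30%-vs-10% mean-WSS
  separation near 2.5 Pa. With pressure boundary conditions the capillary
  flow gain is bounded by (y+1)/(0.7y+1) < 1/0.7, where y is the shared-to-
  capillary resistance ratio, and is further reduced by the total-flow sag;
  pushing y higher while keeping capillary WSS near 14 Pa and all calibres
  physiological exhausts the headroom. A 3-D solver with junction losses,
  or flow-rate (rather than pressure) boundary conditions, would likely
  amplify the response.
* Order-2 vessels (terminal branches) run hotter than order-1 trunks here,
  whereas the reference observations place second-order arteriole WSS below
  first-order; concentrating the pressure drop in the terminal branches is
  what the dropout physics demands of a 1-D model.
* One synthetic anatomy; no population variability, no real acquisitions.
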