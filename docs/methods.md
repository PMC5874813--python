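# Methods

## Scope and coordinate frame

`ecollim` models the in-air collimation chain of a linac electron beam line:
X-ray jaws (one pair per axis, at different heights) followed by three
square trimmer frames (upper, middle, lower) whose downstream surfaces sit
at configurable z-positions. z is measured from the target plane; the
isocenter is at z = 100 cm and the effective (virtual) electron source at
z = 6 cm, i.e. 94 cm above isocenter. All penumbra distances are taken from
the virtual source. Field sizes are defined at isocenter and projected to
collimator planes through the virtual source point; the sub-millimetre
difference against projecting from the target is accepted.

The package computes fluence geometry and mass only. It does not transport
electrons in matter, compute dose to water, model bremsstrahlung or
collimator-scattered electrons, or evaluate out-of-field leakage dose —
those require Monte Carlo tools and are outside this package's scope.

## Penumbra model

A collimator edge at distance z′ from the source casts, at a downstream
plane z, an error-function penumbra with Gaussian width

σ² = A(E, z′, z) + σ_SW² ((z−z′)/z′)²,

σ_SW = 2.0 cm being the Gaussian virtual-source width (a single value for
all energies, calibrated at one energy in the underlying beam data) and
T_air(E) = 0.00554 E^−1.78 rad²/cm the air scattering power (anchored to the
ICRU 10-MeV value). Three air-scatter terms A are implemented:

* `fermi_eyges` — T·g³/3, the Fermi–Eyges integral ∫T(z−u)²du over the gap
  g = z−z′ alone;
* `upstream_divergence` (default) — T·(z′g²/4 + g³/3). Pencil beams
  arriving at the upstream aperture from a point source carry a
  position-conditional angular variance T·z′/4 (the Fermi–Eyges moments
  give Var(θ|x) = A0 − A1²/A2 = T·z′/4 for constant T), which fans out over
  the gap in addition to the fresh in-gap scattering;
* `divergent_plane` — T·g·z²/6, a literal reading of one published design
  formula; retained for comparison but it produces unphysically wide
  trimmer-gap penumbras.

The default was selected by a desk calibration of the whole design chain
against the published staged weight ledger and jaw-setting table of the
design study this package re-implements; the pure in-gap term
underestimates penumbra widths (and hence all trimmer masses) by ~25–45%,
while the default reproduces the weight ledger to within ~4–10% at every
stage. This is an engineering closure, not a first-principles derivation:
the published study used a scattering-moments transport whose exact moment
set is not reproducible from the printed material.

## Jaw-plane heights

The jaw plane z-positions per axis are not published. Two calibrations are
provided (`design_optimizer`): a projection calibration, using the ratio of
a printed physical jaw half-aperture to its isocenter-projected value
(z from similar triangles through the virtual source), and a penumbra
calibration that root-finds the plane whose modelled penumbra reproduces a
printed isocenter-projected jaw position at a known matching OAR. The
defaults (45.6 cm in-plane, 54.5 cm cross-plane) come from the projection
calibration of the printed 20-MeV jaw settings and are flagged as derived
assumptions; `ecollim calibrate-jaws --inplane 5.1 12.1 --crossplane 4.8 9.3`
reproduces them.

## Stopping-thickness (bevel) law

Full trimmer thickness is 0.53 cm of tungsten alloy at 9.6 g/cm² areal
density (density 18.11 g/cm³ follows from the two numbers); 0.53 cm is the
1%-electron-transmission thickness for a 20-MeV beam and anchors the
energy-dependent law t(E) = 0.53·R(E)/R(20). Two range laws are available:

* `practical_linear` (default): the classic linear practical-range relation
  R_p ≈ 0.521·E − 0.376 g/cm²; only the ratio to the 20-MeV value enters,
  so the material scale cancels. Chosen as default because the full design
  chain then reproduces the published staged weights markedly better than
  the CSDA-shaped alternative (final family masses within ~5–8% rather than
  ~20–25%).
* `csda_table`: an embedded CSDA-style range table for tungsten. No
  published tabulation could be bundled, so the table is *computed* from
  standard stopping-power theory — Berger–Seltzer collision term (mean
  excitation energy 727 eV, Sternheimer density-effect parameters for
  tungsten) plus a radiation-length-based radiative term with an
  incomplete-screening factor — and stored as constants with log-log
  interpolation. Its 10-MeV value (6.19 g/cm²) matches the standard
  tungsten CSDA range to ~1%.

Whether the original design used CSDA range, practical range or a
transmission criterion for the bevel is unstated; the scaled-range law with
a selectable shape is this package's documented choice.

## Cross-section construction

Each trimmer bar profile is built from per-energy anchors
x_a(E) = p(E) + k(OAR_outer(E))·σ(E), where p(E) is the projected upstream
edge, k(·) the inverse error-function offset (k(0.02) = 2.05), and
OAR_outer the outer-edge schedule (2% everywhere for plain bevels;
interpolated linearly in energy from 2% at 6 MeV to 48% at 20 MeV for the
final middle/lower bevel shapes). The required thickness at x is the upper
envelope over energies of t(E) for x ≤ x_a(E); anchors are connected
piecewise-linearly by default (a smooth taper that covers the exact
staircase requirement from above; the staircase is retained behind
`bevel_style="staircase"`). Non-monotone anchors (possible once jaw
positions become energy-dependent) are resolved by the envelope, never an
error. The outer boundary is the lowest-energy anchor and carries t(E_min);
there is no zero-thickness skirt.

Inner edges: the chain is solved bottom-up at the lowest energy. The field
size fixes the lower trimmer inner edge; each upstream aperture is solved
so its penumbra takes the prescribed OAR at the downstream inner edge.
Upper and middle trimmer inner faces are aligned with beam divergence: the
sheared face adds a wedge of area (x_inner/ζ)·t²/2 per bar, included in the
mass and reported separately (≲0.5% of total). The lower trimmer face is
parallel to the central axis.

## Frame mass

Mass is ρ·Σ_bars ∫ t(x)·L(x) dx with mitered (45°) corners: the bar length
L(x) interpolates linearly between the inner and outer extents of the
perpendicular pair, which reproduces the exact ring volume for uniform
thickness. The integrand is piecewise quadratic, so per-segment Simpson
quadrature is exact. A `stacked` convention (each pair spans the full outer
length, pairs stacked in z — corners carry both bars) is provided because
the fabrication joint of the original frames is unknown; it is the main
weight-model uncertainty and the reason mass comparisons carry ±10% bands.
A voxelized 2-D rasterization with fractional cell coverage serves as the
independent oracle (agreement to 0.5% at 0.02-cm resolution in the tests).

## Fluence transport and flatness

`transport_fluence` propagates a uniform divergent fluence plane-by-plane in
fan-line coordinates θ = x/ζ: clip to the aperture, then convolve with the
Gaussian penumbra kernel of the following air gap. Clip discontinuities are
blurred analytically (error-function terms), so a single edge reproduces the
closed-form penumbra to machine precision; the smooth remainder is convolved
on a 0.05-cm grid with a cell-integrated Gaussian kernel. This is a
first-moment (Gaussian) approximation to a full scattering-moments
transport: per-gap kernels are independent, so angular correlations across
collimation levels beyond the upstream-divergence term are neglected.
Flatness applies the uniformity-edge rule: the relative fluence 2 cm inside
the field edge on a major axis may drop at most 2% below the central axis
(evaluated at the lowest energy, the most scattering-prone beam). Diagonal
profiles are approximated by the product of the two major-axis profiles at
r/√2 and are reported, not constrained.

## Optimization machinery

Both optimizers are exhaustive grid enumerations — results are deterministic
and equal to independent re-enumeration, with ties broken toward lowest
mass, then smallest upper, then smallest middle plane position. The plane
search spans 55–93 cm at 0.5-cm steps with ≥2 cm separation (lower trimmer
fixed at 95 cm). The five-parameter inner-edge search (three OARs, two plane
positions) runs three iterations with shrinking steps (1.5/1.0/0.5 % and
cm); each iteration re-centers on the incumbent spanning ±2 steps, clipped
to global bounds — the published iteration bounds follow this pattern but
the exact re-centering rule is our inference. Within an iteration,
candidates are checked against the flatness constraint in ascending-mass
order, so the first feasible candidate is the iteration optimum.

## Pipeline defaults

The family pipeline fixes final trimmer planes at 66/79/95 cm (the published
inner-edge-stage outcome; re-optimization is available behind
`reoptimize_planes`), uses the published per-applicator 6-MeV inner-edge OAR
sets (the 14×14 values sit between the 10×10 and 20×20 templates), jaw OAR
interpolated to 55% at 20 MeV, upper-trimmer thickness scaled to 51%, and
middle/lower outer-edge OAR interpolated 2%→48%. The last two constants were
selected in the original study from Monte Carlo leakage-vs-weight curves,
which are out of scope here, so they enter as configuration constants. Note
the published tables disagree on whether the 10×10 ladder assigns
95/96/96.5% to upper/middle/lower or lower/middle/upper; the pipeline
follows the family table (lower 95, middle 96, upper 96.5).

## Known limitations

* The Gaussian penumbra model, calibrated as above, still reproduces the
  published staged weights only to ~4–10%; the un-beveled starting masses
  sit right at the +10% edge, and the bevel-stage *percentage* saving
  (≈20% vs the published 14.7%) overshoots because the model's
  energy-contrast σ(6 MeV)−σ(20 MeV) at the collimator gaps is larger than
  the published jaw-position table implies.
* The mass-minimizing plane positions land at (65.5, 79.5) cm for the
  10×10 applicator, 2–9 grid steps downstream of the published (61.0,
  77.0); reproducing the published optimum requires jaw planes ~4 cm higher
  than any reading of the printed jaw settings supports, which in turn
  breaks every mass comparison. This is an irreducible fidelity limit of
  the two-term Gaussian model.
* The energy-range comparison (6–20 vs 4–22 MeV starting designs) yields a
  ~42% saving against the published "approximately 30%": the calibrated air
  term grows the 4-MeV widths faster than the original model did.
* Flatness here is in-air fluence flatness; the published acceptance used
  Monte Carlo dose at depth. Designs that pass the analytic rule narrowly
  may still fail a dose-based criterion.
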