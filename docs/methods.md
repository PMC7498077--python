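# Methods

## Scope and model summary

`tuberoot` simulates the harvest-period potato tuber-root system as a
statistical snapshot: no phenology, no soil mechanics, no fibrous roots.
Geotropism, growth randomness and soil resistance enter only statistically,
through the measured distributions of initial angles and total deflection.
The simulator has four layers: parameter distributions, plant topology,
growth trajectories, and organ geometry, with an RRMSE-based validation
loop on root depths.

## Parameter distributions

Each scalar parameter is a `DistributionSpec`, either normal (mu, sigma) or
piecewise-uniform empirical (closed intervals [a_i, b_i] with probabilities
p_i summing to 1 within 1e-6).  Empirical sampling is the inverse-CDF
interval walk; within-interval draws are uniform.  Printed field bins such
as [70°, 85°], [86°, 100°] are stored verbatim, including their 1° gaps —
the boundary convention of the source bins is ambiguous and bridging them
would silently move probability mass.

Fitting (`fit_distribution`) tests normality with Shapiro–Wilk at
alpha = 0.05.  The original workflow only states that a non-parametric SPSS
test separated "significantly normal" parameters from the rest;
Shapiro–Wilk is this package's choice of that test.  Non-normal samples are
binned into k = ceil(1 + log2 n) equal-width intervals (Sturges) with
relative frequencies as probabilities; empty bins are merged into their
neighbour.  Constant samples degenerate to a single zero-width interval.
Integer organ counts are fitted as exact frequency tables (zero-width
intervals over the observed integers): a midpoint-binned continuous law
over integers biases the implied mean by up to half a bin width, while the
frequency table's mean is the sample mean.  Fitting requires at least 8
values per parameter; below that the caller must supply an explicit spec.

Physically nonnegative parameters (radii, lengths, depths, counts,
distances, dimensions) are sampled with rejection of negative draws (at
most 100 attempts, then clamp to 0).  Counts are additionally rounded to
the nearest nonnegative integer.

## Topology

Plants are trees in child-chain storage (first-child / next-sibling
pointers): seed potato (level 1) → underground stem and seminal roots
(level 2) → creeping roots and creeping stems along the stem (level 3) →
one tuber per creeping-stem terminus (level 4).  Rooting distances h_g are
sampled independently per root and clamped to [0, h_j]; coincident rooting
heights are allowed (they differ in radial angle).  When the sampled tuber
count is below the creeping-stem count, the longest stems receive tubers
first; surplus tubers beyond the stem count are dropped with a warning.

## Growth trajectories

A root axis is N = round(l_total / l_unit) unit steps.  The step operator
is the row-vector product [0, l, 0]·R(γ, θ) with

    R(γ, θ) = [[ cosγ,        sinγ,       0],
               [−cosθ·sinγ,   cosθ·cosγ,  sinθ],
               [ sinθ·sinγ,  −sinθ·cosγ,  cosθ]]

applied in an accumulated orientation frame (O ← R·O; step = [0,l,0]·O).
Read literally, the transform chain rotates each translated point about the
global origin, which cannot yield a smooth incremental trajectory; the
accumulated-frame reading reproduces the single-step algebra exactly from
the identity orientation and bends each subsequent step relative to the
direction the tip already has.  Rotations are isometries, so every segment
has length l_unit to floating-point accuracy.

Per-step deflections default to the uniform split (γ_i, θ_i) =
(Ф_radial/N, Ф_axial/N) — bending treated as a uniform change — with an
option to sample each step's deflection from database specs instead.
Default l_unit is 1 mm; smaller units give smoother axes at linear cost,
and the axis geometry converges (chords approach the circular-arc chord
2·(L/Ф)·sin(Ф/2) as l_unit → 0).

Conventions: right-handed frame, z = depth, positive downward, surface at
z = 0, seed-potato center at (0, 0, z0).  The axial placement angle is
measured from the upward underground-stem direction, so direction(θ0) =
(0, sinθ0, −cosθ0): 90° horizontal, 180° straight down.  The radial angle
spins the axis about the vertical from +Y.  A seed-centered frame is
recovered by subtracting (0, 0, z0).  Measured axial angles of 70–160°
therefore map to horizontal-to-steeply-downward roots, as they must.

## Geometry

All meshes are triangle surfaces with consistent outward winding,
watertight by construction, exported via trimesh (OBJ/PLY).

- Seed potato: semi-ellipsoid with semi-axes LS/2, WS/2 and dome depth HS,
  flat face up (a spent seed tuber), closed by a fan cap.
- Underground stem: n_segments stacked cone frusta; ring k has radius
  RD·(1 − rD·k/n_segments) (global linear taper; the alternative per-segment
  reading of the taper was rejected as it makes the profile depend on the
  segment count), with interior ring centers jittered uniformly in
  [−jitter, +jitter]² (default 5 % of RD) for the rough, irregular surface.
- Roots and creeping stems: tubes swept along the growth axis with
  parallel-transport frames (no twist at bends), radius linear from r_g0 to
  r_g1; r_g1 = 0 closes into a cone tip without degenerate faces.
- Tubers: ellipsoids with semi-axes LK/2, WK/2, HK/2, long axis horizontal
  by default (natural lie of stolon-end tubers, configurable).  Shape
  classes by aspect ratio of the two largest dimensions: < 1.15 spherical,
  < 1.8 ellipsoid, else elongated.  The class names are from the source
  material; the numeric cutoffs are this package's choice (none are
  published) and are exposed as module constants.

Volume accuracy: UV-parameterized spheres/hemispheres and 96-gon frusta are
within 2 % of the closed forms at the tested resolutions (32–96), with
error falling at least linearly under resolution doubling.

## Validation

RRMSE (percent) is computed exactly as defined above; boundary values 10,
20 and 30 % are assigned to the worse class, since the published ranges
("between 10 % and 20 %") do not fix the boundaries.  `validate_model`
simulates n plants, extracts per-class trajectory maximum depths, and pairs
them with measured depths by rank: both samples are compared quantile to
quantile (sorted measurements against the matching quantiles of the
simulated sample).  Field and simulated plants share no identity, so rank
pairing is the distributional comparison that invents none.  Simulated
depth is always trajectory-derived, never a redraw of the fitted depth
law — the comparison exercises the growth model end to end.

## Synthetic field campaigns

The full per-variety measurement tables are unavailable, so
`synthetic.default_truth` supplies a complete ground-truth database per
variety code (1 Zaodabai, 2 Helanshiwu, 3 Fujin).  Its one field-derived
component is the published Zaodabai creeping-root axial-angle law; all
other specs are synthetic defaults chosen to be agronomically plausible for
early-maturing varieties at harvest: burial depth ~100 mm, stem height
~140 mm, root lengths 120–180 mm, seminal roots steeply downward
(θ ≈ 150°), creeping organs near horizontal, tuber dimensions 45–75 mm,
per-plant organ counts 2–5.  Root depths then land in the low hundreds of
mm, consistent with the published measured range (≈ 28–210 mm).  Varieties
2 and 3 scale sizes by 0.9/1.1 and use normal axial-angle laws.

Root-depth specs are not free parameters: in a real field the measured
depth is generated by the same trajectories the simulator grows, so each
class's depth law is calibrated by an internal seeded simulation (300
instances per class, growth unit 2 mm) of the truth trajectory parameters
and fitted with the standard model selection.  Without this coupling,
self-validation would measure an inconsistency introduced by the
configuration rather than model error.

`generate_measurements` emulates the excavation protocol: per plant, organ
counts first, then every instance's scalar parameters, all i.i.d. from the
truth specs.  It does not emulate instrument quantization (1° protractor,
0.01 mm caliper), measurement error, within-plant correlation, or plant
selection effects — so passing recovery/validation tests demonstrates
correctness of the fitting and simulation machinery under the assumed
statistical model, not robustness to real field noise.

## Problem sizes and determinism

Default campaigns are 50 plants (the published campaign size); recovery and
self-validation properties are checked over 20 independent seeds, and the
sampler frequency check uses 100,000 draws.  All randomness flows through a
single seedable `numpy.random.Generator` per operation; seeds are recorded
in every artifact, and fixed seeds give bitwise-identical axes, plants and
JSON documents.

## Known limitations

- Axes may cross the soil surface or each other; no collision handling.
- The underground stem is grown vertically; its own measured deflection is
  not modeled beyond the mesh jitter.
- Tuber placement ignores the creeping stem's radius (centers sit exactly
  at the terminal axis point).
- The empirical-law boundary convention (closed intervals with verbatim
  gaps) can leave sub-degree measurement values unrepresentable when specs
  are entered from printed integer bins.
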