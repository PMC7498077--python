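# tuberoot

Statistical 3D simulation of the potato (*Solanum tuberosum* L.) tuber-root
system — the belowground assembly of seed tuber, underground (main) stem,
seminal roots, stolon-borne creeping roots, creeping stems and daughter
tubers — for people who need geometrically explicit root-system models:
harvester/digging-component interaction studies, soil–root aggregate
simulation, and virtual-plant work on tuber crops generally.  Fibrous roots
are deliberately ignored; they are too slim to matter mechanically.

## The model

Every characterization parameter of the system (initial axial angle θ and
radial angle η of each root, initial and tip radii r_g0, r_g1, root length
l, soil depth d, total deflection Ф, organ counts N_g and N_k, rooting
distance h_g, stem radii r_j0/r_j1 and height h_j, seed and tuber
dimensions, burial depth z0) is a random variable fitted from per-plant
field measurements: normal where a Shapiro–Wilk test does not reject
normality, otherwise a piecewise-uniform empirical law — interval
probabilities P_i over bounds [a_i, b_i], sampled by the inverse-CDF walk
(draw u ~ U[0,1], pick interval i with u ∈ (cum_{i-1}, cum_i], draw
uniformly inside it).

A plant is a tree in child-chain (first-child / next-sibling) storage: the
seed potato is the root node, the underground stem and seminal roots form
level 2, creeping roots/stems attach along the stem at level 3, and each
creeping stem carries one tuber at its terminal node (level 4).

Root axes grow by unit-length growth steps.  Each step translates the tip a
unit length l along the local Y axis and deflects it by a radial rotation γ
(about Z) and an axial rotation θ (about X), in the row-vector
homogeneous-transform convention:

    [x₂, y₂, z₂, 1] = [x₁, y₁, z₁, 1] · T(l) · R(γ, θ),
    [0, l, 0] · R(γ, θ) = l · (−cosθ sinγ, cosθ cosγ, sinθ)

with the orientation accumulated per step so the trajectory bends smoothly;
the measured total deflection Ф is spread uniformly over the N = l_total/l
steps.  The finished polyline is rigidly rotated by the initial axial angle
(measured from the upward stem direction: 90° horizontal, 180° straight
down) and the initial radial angle, then translated to its rooting point.
The world frame is right-handed with z the soil depth, positive downward,
surface at z = 0, seed-potato center at (0, 0, z0).

Organs are meshed procedurally: semi-ellipsoid seed potato, stitched
off-axis cone frusta for the rough underground stem, parallel-transport
swept tapering tubes for roots, and ellipsoid tubers classed as spherical,
ellipsoid or elongated by aspect ratio.  Validation compares measured root
depths with trajectory-derived simulated depths via the relative
root-mean-square error,

    RRMSE = 100 · √( (1/n) Σ (OBS_i − SIM_i)² ) / ( (1/n) Σ OBS_i )  [%]

on a four-level scale: < 10 % extremely significant agreement, 10–20 %
significant, 20–30 % general, ≥ 30 % poor.

## Worked example

`examples/` holds one short script per capability.  Running
`python examples/03_validate_depths.py` builds a synthetic 50-plant Zaodabai
field campaign, fits a parameter database from it, simulates 50 plants from
the fitted database, and validates simulated against measured root depths:

```
root class       RRMSE %  level            n
seminal_root        2.62  extremely_significant  195
creeping_root      11.33  significant            242
creeping_stem       6.43  extremely_significant  147
```

Each row is one root class: the RRMSE between the rank-paired measured and
simulated depth distributions, its accuracy level, and the number of depth
pairs.  Values inside 20 % mean the simulated depth distribution is
statistically consistent with the measurements; here the self-consistency
run lands every class at significant or better.

`examples/02_build_plant.py` samples a single plant and exports its organ
meshes:

```
variety Zaodabai, seed 7: 18 organ nodes
  seminal_root    x5
  creeping_root   x5
  creeping_stem   x4
  tuber           x2
seminal-root depths (mm): 211, 234, 235, 239, 241
```

The same pipeline is scriptable from the shell via the `tuberoot` CLI
(`synth`, `fit`, `generate`, `validate`); every artifact embeds the seed
that produced it.

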