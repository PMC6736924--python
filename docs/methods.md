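# Methods

`pneumosim` simulates the abdominal deformation caused by gas
insufflation (pneumoperitoneum) from segmented cross-sectional imaging,
and calibrates the simulation against an insufflated reconstruction of
the same subject.  This note records the model, its parameters, the
numerical choices, and what the synthetic phantom does and does not
establish.

## Model

The abdomen is reduced to four regions: the abdominal–thoracic wall,
the viscera treated as one homogeneous soft body, the peritoneal
boundary between them, and the lungs (segmented for completeness,
inert in the simulation).  Wall and viscera are volume-sampled into
particles of a single global radius on a regular interior grid; their
elasticity comes from overlapping shape-matching clusters — groups of
particles penalized toward the best rigid fit of their rest shape, with
a stiffness in (0, 1] that sets tissue deformability.  The peritoneal
boundary becomes an *inflatable*: one particle per surface vertex
carrying the closed triangulation, stiffened in-plane by one spring per
unique edge, and driven by a volume constraint

&nbsp;&nbsp;&nbsp;&nbsp;C(x) = V(x) − p·V₀,

where V is the signed divergence-theorem volume of the particle surface,
V₀ its rest volume, and p the dimensionless *simulation pressure
factor* — the proxy for insufflation pressure.  Gas insufflation is
simulated by projecting this constraint toward a target volume p·V₀.
Additional *connectivity springs* tie each inflatable particle to its
nearest wall particle (rest length = rest separation, created within
two radii), keeping the gas pocket attached to the wall.  Contact
between regions is particle–particle collision at two radii with
Coulomb-style friction.  Dorsal wall particles lying at least 3 mm
below the centre of mass (dorso-ventral axis, −y) are pinned to
represent the operating table; gravity is zero because both the
deflated and the insufflated configurations are imaged supine, so the
gravitational pre-load cancels out of the comparison.

Only the static post-insufflation equilibrium is claimed; transient
dynamics are heavily damped bookkeeping.

## Solver

Position-based dynamics: each 1/60 s frame is split into 3 substeps
(one collision detection each); each substep predicts positions from
damped velocities, then runs 9 iterations of constraint projection in a
fixed order — clusters, springs, inflatable volume, collisions — and
rebuilds velocities from the positional change.  Key numerical choices:

* **Iteration-corrected stiffness.**  A configured stiffness k is
  applied per iteration as k′ = 1 − (1−k)^(1/9), so its effective value
  is iteration-count independent.  The correction is applied to cluster
  stiffness as well as spring stiffness; raw per-iteration application
  would saturate every grid value ≥ 0.4 to an effective ≈ 1 and erase
  the distinctions the calibration grid is meant to explore.
* **Local relaxation with momentum-exact averaging.**  Within a
  constraint group, corrections are accumulated Jacobi-style and each
  constraint's contribution is divided by the *largest* participation
  count among its members.  Sharing one divisor per constraint keeps
  that constraint's mass-weighted corrections summing to zero, so with
  gravity off and nothing pinned the centre of mass is conserved to
  floating-point round-off; taking the max (not the mean) bounds the
  accumulated correction on any particle by one full constraint
  correction (gain ≤ 1) — a mean divisor measurably over-corrects
  particles with asymmetric participation and can sustain an exact
  period-2 limit cycle instead of settling.
* **Volume line search.**  V(x + s·Δ) along the projection direction is
  an exact cubic in s; each volume step is scaled to land exactly on the
  target volume when the raw Newton step would cross it.  Raw steps
  oscillate across the cubic constraint and crumple the surface;
  incremental capped steps compound the mesh's vertex-area imbalance
  into spurious bumps.  With the line search an isolated sphere inflated
  8-fold in volume doubles its radius to within 1%.
* **Velocity limiter.**  Velocities rebuilt from constraint travel are
  uniformly rescaled so no particle advects farther than half a radius
  per substep.  This is a CFL-style guard for the quasi-static solve;
  uniform scaling preserves total momentum.
* **Collision candidates with margin; rest-overlap exemption.**
  Candidate pairs are gathered at 2.2 radii so pairs resolved to exactly
  the contact distance stay in the candidate set between substeps
  (contact-set flicker otherwise produces a period-2 cycle).  Pairs of
  *different* regions that already interpenetrate in the rest
  configuration — unavoidable, since adjacent region layers are closer
  than two radii by construction — are exempt from collision response,
  the analogue of collision filters/phases in particle engines.  Same-
  region cohesion is the clusters' job; collisions act between regions.
* **Shape matching.**  Per cluster, the optimal rotation comes from the
  SVD-based polar decomposition of the moment matrix with the reflection
  removed; clusters whose current shape is rank-deficient (collinear)
  fall back to the identity rotation.  Member weights are uniform — the
  single global particle radius makes all masses equal.
* **Equilibrium detection.**  The run stops when the per-frame maximum
  particle displacement stays below 10⁻³ × radius for 30 consecutive
  frames (cap 3000 frames).  The stopping rule is necessarily this
  package's own: interactive engines are watched, not stopped.
* **Determinism.**  Fixed constraint ordering, lexicographically sorted
  collision pairs and pure numpy arithmetic make trajectories
  bit-reproducible; the calibration exploits this (see below).

Damping ("12.0 per second") is interpreted as per-substep velocity
attenuation v ← (1 − min(1, 12·dt))·v, dimensionally consistent and
safely clamped.  The shape-friction coefficient (0.35) applies to
contacts against pinned particles — the only "shapes" in this scene —
and the particle friction coefficient (0.25) between free particles.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| time step | 1/60 | s | frame duration |
| substeps | 3 | — | collision detections per frame |
| iterations per substep | 9 | — | constraint projection sweeps |
| cluster spacing factor | 3.33 | ×radius | cluster overlap |
| volume sampling factor | 4 | — | interior grid density (spacing = 4·radius/factor) |
| tissue density | 1.05 | g/cm³ | particle mass |
| damping factor | 12.0 | 1/s | velocity attenuation |
| shape / particle friction | 0.35 / 0.25 | — | Coulomb bounds |
| relaxation | local, 1.0 | — | correction averaging |
| cluster stiffness | 0.4–0.8 (grid) | — | tissue deformability |
| spring stiffness | 0.1–1.0 (grid) | — | membrane stiffness |
| particle radius | 2.2/2.7/3.3 (grid) | mm | discretization scale |
| simulation pressure | 1.0–15.0 step 0.5 (grid) | ×V₀ | gas volume target |

The last four are the calibration dimensions; the published optimum of
this kind of calibration sits mid-grid (cluster 0.6, spring 0.5, radius
2.7 mm, pressure ≈ 9).  Pressure is a volume multiplier, not mmHg;
mapping to gauge pressure would need scans at several insufflation
pressures and is out of scope.

## Calibration

Every grid combination is evaluated by running the full pipeline —
discretize at the combination's radius, simulate to equilibrium at its
pressure, extract the deformed pneumoperitoneum surface — and scoring
the mean per-vertex Euclidean distance to the ground-truth surface,
averaged over datasets with equal weights.  Ties break
lexicographically ascending on (cluster, spring, radius, pressure).
Correspondence is by vertex index when the meshes share topology
(registered same-subject pairs, phantom, engine-generated truth) and by
closest point on the truth surface otherwise.  Errors run simulated →
truth.  Standard deviations are population (÷N).  Non-convergent
combinations score +∞ rather than aborting the search.

The self-consistency harness generates ground truth *with the engine
itself* at known parameters.  Because the pipeline is bit-deterministic,
re-evaluating at the generating combination replays the identical
trajectory and scores exactly zero, strictly below every other
combination — so a grid containing the generating parameters must
return them exactly.  This validates the search machinery end to end;
it does not validate the physics against reality.

## Phantom

No imaging data ships with the package, so a synthetic abdomen stands
in for the scan pairs: nested ellipsoidal shells (skin/wall, a thin
peritoneal gas gap, viscera, an inert lungs blob) with a seeded smooth
degree-2-harmonic asymmetry, rasterized to label volumes by
ray-parity voxelization.  The default is a half-scale porcine-like
torso section (skin semi-axes 36 × 28 × 30 mm) — half-scale matching
the pipeline's own preprocessing convention, and sized so that 0.5 mm
rasterization yields a wall surface above 100 k faces at a tractable
grid.  The ground-truth "insufflated" twin is analytic: the ventral
wall and the attached peritoneal surface are displaced outward along
the radial direction by a smooth bump (weight max(0, û_y)², amplitude
6 mm by default), the viscera yield dorsally by a compensating amount
bounded by the available gap, and vertex topology is shared
index-for-index with the deflated state.

What the phantom establishes: the imaging chain (rasterize → extract →
decimate → scale) preserves geometry; the metrics reproduce known
displacement fields; the discretizer and solver behave lawfully
(momentum, monotone inflation, stability); and calibration recovers
engine-generated truth exactly.  What it does not establish: agreement
with real tissue.  The analytic bump is deliberately localized, whereas
the elastic equilibrium spreads the volume gain over the whole free
boundary, so the simulated equilibrium does not reproduce the analytic
truth closely — scoring against it measures that mode difference, not
solver error.  Real validation needs real scan pairs.

## Known limitations

* A single particle layer is all a 2–4 mm wall shell can carry at
  radius ≈ 2.7 mm.  With rest-overlap collision exemptions, a pressed
  membrane can partially slip around such a layer (seen as ~2 mm of
  dorsal/lateral ballooning on the half-scale phantom); the
  connectivity springs bound, but do not eliminate, this leakage —
  which is exactly why they exist.  Re-enabling collisions for
  rest-overlapping pairs at their rest separation was tried and
  rejected: it does not stop the slip (pairwise distance floors cannot
  seal a surface) and slows convergence several-fold.
* Only inter-region collisions are handled; the skin surface cannot
  self-collide.
* Gravity compensation for lateral decubitus positioning, per-organ
  modelling, and mmHg calibration are out of scope.
* Decimation refuses (correctly) to coarsen a thin two-shell wall
  beyond the point where triangles outgrow the shell separation.

## Test scale

Simulation tests run on reduced phantoms chosen for the property under
test: a ~1,300-particle half-scale phantom for parameter recovery
(3 × 3 × 5 grid, exact recovery), and a ~400-particle phantom for the
10⁴-frame stability runs at the calibration-grid corner combinations
and for the pressure-monotonicity sweep.  Problem sizes are stated in
the tests themselves; all quantitative tolerances are the ones quoted
above.
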