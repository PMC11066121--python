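# Methods

## Scope and coordinate conventions

`emnav` simulates the computational chain of an EM-tracked assistance
system for endoscopic transgastric necrosectomy.  Two right-handed
millimetre frames are used throughout:

- **image space** — the CT/virtual frame of the phantom; origin at the
  torso centroid, +x right, +y anterior, +z superior;
- **tracking space** — the field-generator frame; origin at the tabletop
  generator centre, +z up.

Rotations are unit quaternions, scalar-first `(w, x, y, z)`, normalized
and stored on the canonical hemisphere `w ≥ 0` so every rotation has one
representation.  The local +z axis of a 6-DoF pose is the instrument
axis pointing out of the sensor/endoscope tip; the effective tip is the
sensor origin advanced `tip_offset` (default 5 mm) along that axis,
matching a sensor protruding from the working channel.

## Registration

`horn_register` solves absolute orientation in closed form: with centred
point sets `p̃_i` (tracking) and `q̃_i` (image), the optimal rotation is
the eigenvector of the largest eigenvalue of the 4×4 symmetric matrix
built from the cross-covariance `S = Σ p̃_i q̃_iᵀ`, taken on the
non-negative-scalar hemisphere; the translation maps centroid onto
centroid.  Rigid only — no scaling — since phantom and image are
metrically consistent.  Correspondence is by marker id; there is no
point matching.  Degeneracy is screened before fitting: the constellation
is rejected when the second singular value of the centred point matrix
falls below 1e-6 of the largest (collinear or coincident fiducials leave
a rotation axis unconstrained).  A named subset (≥ 3 ids) can restrict
the fit, expressing a workflow where only three of the six registration
markers are digitized; the default uses all six.

The implementation is cross-checked in the test suite against an
independent SVD (Kabsch) solution and against exact recovery of random
rigid transforms; both agree to ≤ 1e-9.

### Error metrics

- **FRE** `= sqrt(mean ‖q_i − T(p_i)‖²)` over the fiducials used.
- **TRE** is estimated by Monte Carlo (`monte_carlo_tre`): perturb the
  digitized fiducials by isotropic per-axis Gaussian noise σ,
  re-register, map the target, and take the RMS displacement from the
  noise-free mapping.  First-order reference values used in the tests:
  `E[FRE²] = (1 − 2/N)·3σ²` and, at the fiducial centroid,
  `RMS TRE = σ√(3/N)`.  These are small-noise approximations; at the
  σ = 0.3 mm used in the checks (fiducial spread ~100 mm) higher-order
  terms are negligible relative to the 3–5 % test tolerances.
- **Navigation error** (primary outcome): Euclidean distance between the
  registered tip position and the target marker centre at the final
  valid sample of an approach.

Monte-Carlo registration is vectorized (batched 4×4 eigendecomposition),
so 10⁴ replicates run in about a second.

## Synthetic phantom

No patient geometry is published, so the phantom is parametric:
superellipsoids `|x/a|^p + |y/b|^p + |z/c|^p = 1` for stomach
(a,b,c = 55, 40, 85 mm, p = 2.5), necrotic cavity (35, 28, 45 mm,
p = 2.2, posterior-inferior to the stomach) and torso shell
(150, 110, 220 mm, p = 2.0) — adult-torso-scale shapes with the right
topology for the navigation math, which depends only on marker layout.
Meshes are icospheres (subdivision 4, 5120 faces) projected radially onto
the analytic surface, hence watertight by construction; at this
resolution the enclosed volume agrees with the analytic superellipsoid
volume `8abc·Γ(1+1/p)³/Γ(1+3/p)` to ~0.3 %.

Markers are placed on the analytic surfaces with a seeded sampler that
enforces pairwise angular separation (and avoids the esophagus-entry and
aperture directions): 5 mural targets and 3 fiducials on the stomach,
2 extramural targets and 2 fiducials on the necrosis, 1 fiducial at half
radius inside the torso.  Ids are `T1..T7`, `F1..F6`.  The transgastric
access is modelled as a *logical* aperture — the stomach-wall point
facing the necrosis, through which extramural trajectories are routed —
rather than a boolean cut, keeping the meshes watertight.  A 1.0 mm
surface-adhesion tolerance covers mesh discretization error.

## Tracking simulation

`GroundTruth.build` places the supine phantom over the generator: image
+y (anterior) maps up, image +z (superior) to a horizontal axis, torso
centroid at plate height (110 mm, the bench setup's generator offset)
plus the anterior half-thickness; a seed adds a uniform yaw, ≤ 3° tilt
and ≤ 40 mm tabletop offset.  The valid tracking box defaults to
x, y ∈ [−275, 275] mm, z ∈ [50, 600] mm — a stated assumption at the
scale of a tabletop EM generator, since no vendor figures are modelled.
Samples outside the box are flagged invalid and skipped downstream, not
interpolated.

Noise model (all overridable):

| parameter        | default | meaning                                    |
|------------------|---------|--------------------------------------------|
| `sigma_pos`      | 0.2 mm  | per-axis Gaussian sensor position noise    |
| `sigma_rot_deg`  | 0.2°    | axis-angle orientation noise (random axis) |
| `operator_sigma` | 1.5 mm  | per-axis Gaussian terminal touch error     |

Orientation noise is applied as a rotation about a uniformly random axis
with Gaussian angle, which keeps the perturbation a proper rotation;
per-component quaternion noise would not.  The rng draw order per sample
is fixed (3 position, 3 axis, 1 angle normals) so streams stay aligned
across noise settings.  All stages draw from independent sub-streams of
one master seed via `SeedSequence([seed, crc32(stage)])`; derived seeds
stay below 2³¹.

An approach trajectory is a cubic spline through anatomical waypoints
(esophagus entry → stomach interior → [aperture for extramural targets]
→ final tip) with sinusoidal slow-in easing; the final tip equals the
target plus the per-axis operator error, the sensor pose trails the tip
by `tip_offset` along the spline tangent, and every sample passes through
the sensor-noise model.  With all noise zero the chain
digitize → register → navigate closes on the targets to ≤ 1e-9 mm.

## Evaluation

Run summaries use half-up decimal rounding — one decimal for mm, two for
ratings — which reproduces all internally consistent published means.
The packaged bench table contains one printed run mean (6.5 mm for the
sixth run) that is inconsistent with its own per-target values (they
average 5.5 mm, a likely typesetting error); the report always
recomputes, so 5.5 is what it prints.  Run comparison uses the classical
equal-variance one-way ANOVA (`scipy.stats.f_oneway` behind a validated
contract), with the all-constant degenerate case reported as F = 0,
p = 1.  Procedure time is the simulated session duration (targets ×
approach duration) and is not meant to match human procedure times.

## What the simulation does and does not show

The generator emulates the *error structure* of the bench experiment —
fiducial digitization noise propagating through a six-marker Horn
registration, sensor jitter, and a human terminal placement error — under
which 20-seed studies produce run-mean navigation errors of roughly
2–3.5 mm, overlapping the 2.6–6.5 mm band reported on the physical bench.
It does not model EM field distortion, sensor-distance-dependent jitter,
phantom surface roughness (a major bench error source), operator learning
effects, or differences between display modes; the mode label on a run is
metadata.  Absolute bench quantities — FRE of 1.1–1.2 mm, specific
per-target errors, procedure times — are therefore *not* reproduced, only
their governing relationships.  Simulated FRE at default noise is
≈ 0.28 mm, the value the first-order law predicts for six fiducials at
0.2 mm digitization noise.

## Problem sizes

Default test and acceptance workloads: 10³ random transforms for exact
recovery, 10⁴ Monte-Carlo replicates for the FRE/TRE laws, 20 seeded
sessions (2 s × 20 Hz approaches) for the calibration check, and 10³
null simulations for the ANOVA type-I rate — sizes at which every
sampling error is several times smaller than the tolerance it is checked
against.

## Known limitations

- The phantom is representative, not patient-derived; marker coordinates
  are synthetic.
- Trajectories ignore collision with the phantom walls; they are smooth
  curves through anatomical waypoints, adequate for targeting-error
  statistics but not for path-planning studies.
- First-order FRE/TRE laws are used as references only; no general
  Fitzpatrick TRE formula (with the fiducial moment terms) is
  implemented beyond the centroid limit.
- The sensor-view mode is reduced to a cone-visibility computation
  (distance and off-axis angle per marker); no rendering.
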