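# Methods

`gastroflow` asks a mechanistic question about palliative surgery for
gastric outlet obstruction: why does the stomach-partitioning
gastrojejunostomy (SPGJ) empty better than the conventional
gastrojejunostomy (CGJ)?  It answers it twice — once with fluid dynamics on
a reconstructed upper-GI tract, once with statistics on a published
73-patient registry — and this note records the models, the parameters that
matter, and the choices made where the design was genuinely open.

## 1. Parametric anatomy

The patient-specific CT-derived tract is replaced by a parametric implicit
geometry (signed-distance primitives, millimetre coordinates, y up and z
anterior).  Its pieces:

* **Esophagus** (100 mm long, 24 mm ID): vertical above, bending at the
  cardia so the entering stream is launched along the gastric canal — the
  lesser-curvature channel that physiologically conducts liquids toward the
  antrum.
* **Stomach**: a J-shaped centreline template with elliptical cross-sections
  (anterior-posterior flattening 0.6), scaled by the greater-curvature
  length (280 mm) and maximum lumen diameter (80 mm).  The body shape is
  not a printed quantity; the template models a gastric-filling-phase
  stomach of a BMI-22 adult.
* **Gastrojejunal anastomosis**: a stapled side-to-side stoma, modelled as a
  45 mm x ~20 mm rounded-slot channel through the **posterior wall** of the
  distal corpus (60 mm along the greater curvature from the cardia — the
  "about 5 cm proximal to the tumour" placement of the operative
  description), opening into a retrogastric jejunum.  The posterior
  placement matters: the coronal food stream must turn out of its plane to
  exit, exactly as with a real apposed-loop stoma, and the resulting
  geometry is deliberately not mirror-symmetric, which pins the jet's
  attachment (a perfectly planar layout is bistable at the operating
  Reynolds number).
* **Duodenojejunal conduit** (25 mm ID): from the pylorus (15 mm ID) through
  a C-loop descending into the retrogastric plane, rejoining the afferent
  limb just distal to the stoma; the loop amplitude is solved by bisection
  so the pylorus-to-anastomosis path length equals its parameter (350 mm).
* **Efferent limb**: 150 mm from the stoma to the outflow plane, a length
  chosen once so the outlet sits far from the junction recirculation.

The SPGJ variant subtracts a 10 mm-thick partition wall across the stomach
immediately distal to the stoma (the corpus-antrum junction), leaving a
channel of the configured width (default 20 mm; the surgical literature
quotes 2-3 cm) along the lesser curvature.  CGJ and SPGJ are bitwise
identical outside the partition slab.  A `stenosis_factor` in (0,1] can
narrow the pyloroduodenal path to emulate the obstruction itself; the
default is 1.0 (patent), matching the simulated reference configuration.

A planar mode (`discretize(..., planar=True)`) meshes the coronal mid-plane
as a single cell layer with free-slip symmetry faces; it served the design
exploration and remains a supported, tested feature, but the study runs in
3D because the posterior-wall stoma has no mid-plane representation.

## 2. Discretization

The lumen is voxelized on a uniform cubic grid (cells are fluid when their
centre is inside the implicit surface; the largest connected component is
kept; fluid beyond the inflow/outflow port planes is clipped).  Wall faces
store the distance from the cell centre to the true wall along the face
normal, recovered from the signed-distance field and clamped to
[0.1h, 1.2h]; wall shear acts over that distance instead of the naive h/2.
This sub-cell correction replaces a near-wall refinement level: the
Hagen-Poiseuille pressure drop of a 24 mm tube is reproduced within 3% at
h = 2 mm (12 cells across the diameter).

Study cell sizes: h = 4 mm, with h = 5 mm as the grid-convergence partner.
The narrowest channel of the default anatomy (the 15 mm pylorus) keeps
~4 cells across at h = 4; `discretize` refuses cell sizes coarser than half
the narrowest channel.

## 3. Flow model

Steady incompressible laminar Navier-Stokes with water properties
(rho = 998.2 kg/m^3, mu = 1.003e-3 Pa s).  Boundary conditions: steady
uniform 0.04 m/s inflow at the esophageal inlet (a parabolic profile is
available for validation runs), traction-free outflow (zero gauge pressure,
zero normal velocity gradient), no-slip rigid walls.  The configuration
Reynolds number is ~950; the solver refuses configurations beyond Re 2000.

Discretization and coupling: collocated finite volumes with SIMPLE
pressure-velocity coupling and Rhie-Chow face-flux interpolation, central
diffusion, and second-order upwind convection applied as a minmod-limited
deferred correction over first-order upwind.  Residuals are normalized by
their largest value over the first five outer iterations; convergence
requires all scaled residuals below 1e-5.  The pressure-correction matrix
is refactorized (sparse LU) whenever its Rhie-Chow coefficients drift more
than 2% from the factorized values.  Under-relaxation defaults are 0.7
(momentum) / 0.3 (pressure).

**Scheme used for the anatomy runs.**  On the reconstructed tract the
limited second-order outer iteration has no affordable fixed point: the
gastric jet at Re ~ 950 is only marginally steady, and the iteration either
cycles at scaled residuals ~1e-2..1e-1 or needs ~10^4 iterations at very
deep under-relaxation (~10 minutes per solve).  The comparative study
therefore runs first-order upwind with alpha = 0.4/0.15, which converges to
1e-5 in ~10^3 iterations (~20 s per variant at h = 4).  The validation
suite exercises the second-order path on the pipe-flow oracle.  The cost of
this choice is extra numerical diffusion of the gastric jet, discussed
under limitations.

A z-mirror symmetry projection (`symmetrize_z`) exists for mirror-symmetric
meshes; the final anatomy is intentionally asymmetric (posterior stoma), so
it is off by default.

### Grid-convergence gate

Following the reference protocol, the pipeline solves each variant at two
resolutions and reports the relative L2 difference of the velocity fields
at shared probe points (the coarse mesh's cell centres); the gate passes
below 5%.  Resolved pipe flow passes easily.  **On the anatomy the gate
does not pass at single-CPU resolutions** (24-31% between successive
affordable grids, h = 6.4...3.2 mm): the under-resolved jet's landing point
and strength still move with h.  The pipeline records the percentage and
warns (set `require_independence=True` to make it fatal).  The integral
comparison is much more grid-robust than the fields themselves — the
pyloric flow split, the retention-time ratio and the speed means keep their
values and ordering across all four resolutions tested — which is why the
comparative metrics are still reported; the field-level gate is reported
honestly as failed.

## 4. Particle model

Food is tracked as a one-way-coupled discrete phase:
du_p/dt = F_D (u - u_p) + F_x with F_D = 18 mu / (rho_p d_p^2) (C_D Re/24),
Re = rho d_p |u_p - u| / mu.  Defaults: rho_p = 1300 kg/m^3, d_p = 50 nm
(as specified for the reference food particle; a 50 um preset exists —
both are dynamically indistinguishable tracers, with momentum response
times of 1.8e-10 s resp. 1.8e-4 s).  The drag correlation is
Schiller-Naumann, which reduces to Stokes at the operative Re ~ 1e-4; pure
Stokes is selectable for the closed-form oracles.  The optional body force
F_x (default off) has a buoyancy-corrected gravity preset; the reference
configuration reports no orientation, so no gravity is applied by default.

Integration is semi-implicit trapezoidal (drag implicit in u_p, carrier
velocity explicit), A-stable for the stiff linear drag term and second
order in dt.  Time steps are per-particle adaptive, 0.2 x cell size /
particle speed, clamped to [1e-4 s, 0.25 s].  Walls reflect specularly with
speed preserved exactly; the inlet and outlet planes are escape boundaries.
Injection is uniform over the inlet disc (seeded, deterministic), with the
initial particle velocity equal to the local fluid velocity.

Because steps are adaptive, the "mean instantaneous speed" of a trajectory
is time-weighted by default (equivalent to sample-weighting under a uniform
output cadence); sample weighting is available.  Means are over escaped
particles only.  Cohorts default to N = 1000 particles and a 600 s window;
particles still inside at the deadline count as timed out (warning above
10%).

## 5. Emptying metrics

For each converged variant: signed volumetric flux through the pyloric and
anastomotic cross-sections (axis-aligned face cuts selected by the conduit
primitive; positive = stomach toward bowel; the two fluxes must close with
the inflow within 0.5%), area-weighted inlet-minus-outlet pressure drop,
mean retention time, and mean particle speed (mm/s).  The comparison report
carries the four headline contrasts: SPGJ pyloric flux as % of CGJ,
relative pressure-drop reduction, CGJ/SPGJ retention-time ratio, and the
two mean speeds.

What the model shows at the study scale, and what it cannot: the mechanism
under study appears clearly — the canal stream sweeps past the posterior
stoma into the antrum in CGJ, sustaining forward pyloric flow (~4% of
inflow) and a slow long-path particle subpopulation, while the SPGJ
partition reduces the pyloric throughflow to numerically zero and shortens
residence.  The pyloric-flow suppression and the retention-time ratio are
therefore reproduced in direction and magnitude class.  Two quantities are
not reproduced: the inlet-outlet pressure-drop reduction (the reference
reports 9%; this model gives ~-1%, because at desk-scale resolution the
numerically diffused jet sends only ~4% of inflow through the long
duodenojejunal loop, whose extra dissipation is then invisible against the
~3-4 Pa base drop) and, marginally, the CGJ mean particle speed (~33-36
mm/s vs 22 mm/s reported; the synthetic tract's conduits are crossed
quickly, and the speed mean has a heavy slow tail from loop-transiting
particles, making it seed-sensitive at the band edge).

## 6. Clinical statistics

The registry itself is unpublished; its group-level counts are embedded
verbatim.  `rebuild_tables` recomputes every derivable percentage and tests
every categorical contrast: Fisher's exact test for 2x2 collapses, Pearson
chi-square over non-empty levels for wider tables (the source names only a
"non-parametric test"; the exact test is the reproducible primary, the
chi-square the cross-check).  Confirmation means the recomputed p falls on
the printed side of 0.05, or below a printed bound such as <0.001.
Continuous rows (times as median/IQR, labs as mean±sd) cannot be re-tested
without per-patient data and serve only as generator targets.

CONUT scoring uses the standard component cut-offs in SI units (albumin
g/L: >=35 -> 0, 30-34.9 -> 2, 25-29.9 -> 4, <25 -> 6; lymphocytes 1e9/L:
>=1.6 -> 0, 1.2-1.59 -> 1, 0.8-1.19 -> 2, <0.8 -> 3; cholesterol mmol/L:
>=4.66 -> 0, 3.62-4.65 -> 1, 2.59-3.61 -> 2, <2.59 -> 3), with severity
bands normal 0-1 / light 2-4 / moderate 5-8 / severe 9-12.

The synthetic cohort generator reproduces the categorical marginals exactly
by construction (sex, disease, approach, complications with Clavien-Dindo
grades, DGE grades, GOOSS pre/post) and draws continuous variables from
printed-moment-matched distributions: labs from normals, day counts from
log-normals matched to the printed median and IQR
(sigma = (ln q3 - ln q1) / (2 z_0.75)), rounded to whole days.  Each
record's CONUT score is computed from its own sampled labs, so records are
internally consistent; the CONUT band distribution then matches the printed
one in shape, not count-for-count.  Passing tests show the pipeline handles
realistically-shaped registry data; they validate no clinical claim beyond
the printed summaries.

## 7. Numerical choices and degenerate inputs

* Zero inlet velocity returns the exact null field without iterating.
* Geometry in mm, solver and tracking in SI metres; the conversion happens
  once, inside `discretize`.
* Port planes are snapped to grid face planes; lumen beyond them is
  clipped.
* Cross-section cuts refuse to report flux when open fluid on the cut plane
  extends beyond the selected conduit (incomplete-cut detection by
  plane-face adjacency).
* Marching-cubes surfacing offsets its sampling lattice by 0.317 h so the
  zero level set never coincides with lattice points.
* Particle reflection mirrors position and velocity across the local
  signed-distance normal (up to 4 bounces), then projects degenerate corner
  cases just inside the wall.
* Fisher's exact test and the chi-square come from scipy; the test suite
  cross-checks the exact test against a direct hypergeometric enumeration.

## 8. Problem sizes

The study resolution is h = 4 mm (~12,300 fluid cells per variant, gated
against h = 5 mm) with 1000 particles per cohort and a 600 s tracking
window; the validation tube runs at h = 2 mm (5600 cells).  A full
comparative study (two variants, two resolutions each, two cohorts)
completes in roughly six minutes on one CPU.

## 9. Known limitations

* Rigid walls, no peristalsis, no fluid-structure interaction; steady flow
  only.  The emptying contrast is purely geometric/inertial.
* The gastric jet is under-resolved at the study cell sizes: field-level
  grid convergence is not reached (see the gate discussion), first-order
  convection adds diffusion, and consequently the pressure-drop contrast of
  the reference is not reproduced.  Integral split/retention metrics are
  grid-robust, the velocity fields are not.
* Newtonian water stands in for gastric contents; no non-Newtonian
  rheology, thermal effects, two-way particle coupling, or Brownian motion.
* The voxel wall is a staircase with sub-cell shear correction — adequate
  for laminar internal flow at the validated tolerances, not for wall
  shear-stress maps.
* One anatomy template: no inter-patient variability; the clinical module
  is bound to the printed group-level summaries.
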