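# Methods

## Physical model

The forward problem is the quasistatic (purely conductive) approximation to
Maxwell's equations: at TTF carrier frequencies (~200 kHz) wave propagation
and, in this model, capacitive effects are neglected, leaving the
generalized Laplace equation

    div( sigma(x) grad phi ) = 0        in the head,
    sigma dphi/dn = j(x)                on the outer surface,

with j the injected current density under the electrodes and zero elsewhere.
sigma is a per-element 3x3 tensor (S/m); all compartments are isotropic by
default. Permittivity is omitted deliberately: the comparison of montages
and the dose-response conversion both operate on the real conductive field
magnitude.

Electrodes are modeled as uniform-current-density footprints (pure Neumann
boundary): each electrode's signed share of the total current is spread over
the boundary triangles whose centroids lie within the electrode radius of
its center, proportionally to triangle area. We do not use the complete
electrode model — contact impedances of the gel/dura interface are unknown,
and uniform flux is the standard simplification for TTF patches. A patch's
total current is split equally over its nine disks (and a 2x2 sub-array
splits a disk's current in four): current-controlled stimulation with equal
splitting is reproducible without modeling lead and gel impedances, at the
cost of ignoring the slight current redistribution an isopotential coupling
would produce.

## Discretization and solver

P1 (linear) tetrahedral finite elements; the element field is constant,
E = -grad phi, reported in V/cm. Node coordinates are kept in mm and
converted to meters at assembly, so potentials come out in volts.

The pure Neumann operator is symmetric positive-semidefinite with the
constants as null space (row sums are zero). The zero-mean potential gauge
is imposed by a Lagrange-multiplier bordering rather than by pinning a node:
it is symmetric and mesh-independent. The bordered system is factorized
once with sparse LU and reused for every right-hand side; this makes the
101-electrode lead-field basis essentially free after the first solve, and
every one of the 5050 pair fields is then a difference of two basis
solutions scaled by the injected current (superposition holds exactly in
the discrete system; tests verify 1e-8 agreement with direct pair solves
and 1e-10 linearity in current).

Degenerate (near-zero-volume) elements abort assembly with the element id.
Probing the piecewise-constant field at a point is done by volume-weighted
averaging of element fields within about one edge length (a fixed radius
when comparing meshes of different resolution, so all levels are smoothed
alike).

## Synthetic head models

The study's MRI-derived meshes are not available, so the generator builds
the standard validation geometry instead: nested spherical compartments.
Default interfaces 92 / 86 / 80 / 78 / 60 mm (skin, compact skull, CSF, GM,
WM) approximate adult head dimensions; a spongy-bone sublayer (84.5-81.5 mm)
is available as a compact/spongy/compact sandwich. Conductivities: skin
0.465, compact skull 0.007, spongy skull 0.025, CSF 1.65, GM 0.276,
WM 0.126, eye 1.5, muscle 0.4, tumor shell 0.24, tumor core 1.0, resection
cavity = CSF (all S/m). For intracranial runs all compartments outside the
CSF are removed and the CSF surface becomes the active boundary — implanted
electrodes are insulated on the outside, and skull conductivity is far below
CSF/brain, so the truncation error is small (it slightly overestimates
intracranial fields).

Meshing places node shells exactly on every compartment interface
(conforming boundaries), fills the radial gaps with Fibonacci-lattice
shells, and tetrahedralizes with Delaunay (the ball is convex, so the
Delaunay tetrahedra tile it). Tangential point spacing on each shell is
clamped to twice the nearest radial gap, which prevents tetrahedra from
tunneling through thin layers (the 2-mm CSF layer in particular). Elements
are labeled by centroid radius. Default target edge length is 7 mm — chosen
for desk-scale convergence, not fidelity to any particular clinical mesh;
at that resolution the total volume is within 0.5% of the analytic sphere
and each compartment within ~2%.

Tumors are spheres: shell with optional nested core and optional resection
cavity, strictly decreasing radii, required to displace brain tissue (GM/WM)
only. Tumor interfaces get their own conforming refinement shells (local
spacing ~ r/3), after which centroid relabeling reproduces part volumes to
about -5% at default resolution (the polyhedral ball underestimates the
sphere; the sign is systematic, the magnitude shrinks with refinement). The
three presets mimic the study's cases qualitatively: superficial 12-mm
tumor with a 7-mm resection cavity, deep central 10-mm tumor with a 6-mm
core, inferior 9-mm tumor.

White-matter anisotropy is available only as a synthetic radial/tangential
option (ratio sigma_radial/sigma_tangential with the geometric mean pinned
at 0.126 S/m); deriving tensors from diffusion imaging is out of scope
because there is no diffusion data for a synthetic sphere.

## Electrode layouts

Transcranial montages use 3x3 patches (22 mm vertical / 33 mm horizontal
center spacing, 10-mm disk radius, 2.5-mm height kept as metadata) mapped
onto the skin sphere with the exponential map, which preserves the grid
spacings as arc lengths. Twelve montages sweep the anteroposterior patch
pair around the vertical axis in 15° steps; five more reproduce montages
from earlier modeling studies (anteroposterior with lowered posterior patch,
top/back, above the ears, top/neck, behind the ears) — their sphere-frame
angles are approximations, since the originals are defined on realistic
anatomy without published coordinates.

The intracranial layout spreads 61 electrodes over upper rings in a
10-10-style angular subdivision and 40 over two lower rings (colatitudes
105° and 120°), avoiding a +/-8-mm interhemispheric midline band on the
superior surface and an inferior exclusion cap below colatitude 135°
(standing in for the tentorium/brainstem constraint, which the source
describes only qualitatively). One reference electrode sits inferiorly on
the brainstem region; it anchors the lead-field basis and never joins
stimulation pairs. Minimum center spacing exceeds the 20-mm electrode
diameter. Ring counts are fixed (4+8+12+16+21 upper, 20+20 lower) so the
layout is deterministic and always yields 101 stimulation electrodes.

## Dose response

TER(E) = 0.4057 E^3 - 1.713 E^2 + 2.941 E - 1.542, valid on the measured
range 1.10-2.40 V/cm, set to 0 below 1.10 and held at TER(2.40) = 1.26
above 2.40. The function is therefore discontinuous at 1.10 V/cm (the cubic
is ~0.1604 there); we adopt the closed-on-the-right convention,
TER(1.10) = cubic value. The cubic is strictly increasing on the capped
interval (checked at construction), so the inverse is unique; TER = 1 gives
E = 2.23 V/cm by bracketed root finding (tolerance 1e-10). Inverting a TER
level below the jump (0 < t < 0.1604) returns 1.10 V/cm — the smallest field
at which that level is met — which is the convention the coverage criteria
need. `refit_polynomial` exists for user-supplied dose-response data; the
printed coefficients are authoritative otherwise because the underlying in
vitro points are not tabulated numerically.

## Optimization

The ROI is all tumor tissue (shell plus core where present; the CSF-filled
resection cavity is not tumor). Coverage is volume-weighted: the percentage
of ROI volume meeting a criterion, with strict inequalities (TER > 0,
TER > 1, E > tau). TER criteria are converted to field thresholds through
the monotone dose response (TER > 0 <=> E >= 1.10 V/cm with the closed
boundary; TER > 1 <=> E > 2.2322 V/cm), so a full current sweep per
configuration is a sort of per-element crossing currents tau/|E_unit|
followed by cumulative-volume lookups — no field is recomputed per current.
The current grid is 2000 points linearly spaced on [0, 2] A with both
endpoints included (I = 0 gives 0% coverage by definition).

Pareto curves use the 101 integer coverage bins p = 0..100 with the
criterion "coverage >= p"; each bin records the minimum current over all
configurations and the achieving configuration, ties broken by ascending
configuration id. Monotonicity of the curve is asserted, not enforced. The
optimal montage minimizes the current for TER > 1 in >= 90% of the ROI;
the top-k (default 5) near-optimal list is the exhaustive ranking's head.
Focality is not penalized — the objective is maximal effect inside the ROI.
The threshold sweep repeats the analysis for E > tau, tau = 1.0..3.0 V/cm
in 0.1 steps; by linearity the required-current curve for 2*tau is exactly
twice the curve for tau.

## Verification oracle

The analytic potential of a surface point-current source on a concentric
multilayer sphere is a Legendre series; per degree n the layer coefficients
solve the continuity conditions (potential and normal current density) plus
the outer Neumann condition. The radial factors are written in the
normalized form alpha (r/r_out)^n + beta (r/r_in)^-(n+1) per layer to avoid
overflow at high n; default truncation N = 200 with a tail-magnitude check
that raises if the last 10 terms still contribute > 0.1%. On one layer the
series sums to the classical closed form, kept as an independent
cross-check. The field is the term-by-term gradient (checked against
central differences to 0.5%).

FEM-vs-oracle comparisons use disk electrodes in the FEM against point
sources in the oracle, so probes stay > 2 electrode radii from the
electrodes, where the disk/point difference has decayed. At the default
7-mm resolution the probed field magnitudes agree to < 5% (mean < 1%), and
the RMS error falls monotonically over the 16/11/7-mm refinement ladder.
The mirror-symmetry check runs on a mesh whose node set is symmetrized
about the electrode-axis plane: on the standard (asymmetric) Fibonacci mesh
the discretization itself breaks symmetry at the 1-2% level, which would
test the mesh, not the solver.

## Problem sizes and determinism

The end-to-end runs use the default 7-mm meshes (~16k nodes intracranial,
~20k nodes full head), the full 101-electrode lead field, all 5050 pairs and
the 2000-point current grid; one such run takes well under a minute on one
CPU, and the complete three-case, two-mode analysis a few minutes. Meshes
are deterministic given the seed (Fibonacci lattices with seeded per-shell
phases), electrode layouts are deterministic by construction, and the
sparse LU solves are deterministic for a fixed mesh, so identical
configurations reproduce byte-identical curve tables. Pipeline stages are
cached on disk keyed by a content hash of the configuration fields that
feed them; changing any upstream field invalidates downstream caches.

## Known limitations

- Spherical geometry: no cortical folding, no eye/muscle compartments
  (labels supported, geometry not generated), no skull thickness variation
  — absolute currents and coverage differ from realistic-anatomy models
  (which report larger transcranial/intracranial contrasts), so results
  here support method-level conclusions, not patient-level ones.
- Uniform-flux electrodes; no contact impedance or gel chemistry.
- Real conductive quasistatics only: no capacitive effects, no frequency
  dependence, no interleaved multi-direction scheduling (pairs can be
  selected post hoc, but field interleaving is not simulated).
- The dose response is a single in vitro glioma curve; no cell-line or
  time-on-therapy effects.
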