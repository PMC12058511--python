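# Methods

`lecmech` models and measures the shape of lymphatic capillary endothelial
cells (LECs).  Capillary LECs are "oak leaf" or puzzle-shaped: their borders
carry alternating convex lobes and concave necks that interdigitate with
neighbours and overlap them, forming the primary fluid entry route into the
lymphatic network.  The package asks, computationally, what this shape buys the
monolayer mechanically, and provides the quantification operators used to
describe the shape and its junctions, together with synthetic-data generators
that make every estimator testable end to end.

## Vessel templates

The vessel wall is a cylinder of diameter 45 µm and length 200 µm (defaults;
the "45 µm wide" dimension is read as the diameter and both are configurable).
All template geometry lives on the unrolled chart `(x, z)` with `x`
circumferential arc length, periodic with period `π·d`, and `z` the axial
coordinate; chords on this chart are geodesics of the developable surface.

The puzzle-cell generator seeds a Voronoi tessellation from a jittered
columns × rows grid of seeds (columns ≥ 3 so no cell neighbours itself across
the periodic seam; 3 × 4 for the default 12 cells, giving three cells around
the circumference as observed in mature capillaries).  Mirror seeds across the
two axial ends close the boundary regions exactly.  Every interior cell–cell
border is then displaced along its normal by a sinusoid of amplitude 4 µm and
wavelength 16 µm (defaults), windowed with `sin(π s/S)` so the junction points
stay fixed, followed by a configurable number of endpoint-pinned smoothing
passes.  Because each border polyline is stored once and shared by both
incident cells, the perturbed cells still partition the surface exactly: cell
interiors stay disjoint, the total area equals the cylinder's lateral area to
round-off, and interior junctions remain tricellular.  Amplitudes large enough
to self-intersect are rejected with a diagnostic.

The defaults were chosen once to emulate the observed morphology: lobes a few
µm deep and ~10–20 µm apart on cells ~50 µm across.  A cross-section of the
lobed template intersects on average ≈ 3.4 cell outlines (reported by
`cells_per_circumference`): the underlying packing is exactly 3 cells around,
and interdigitating lobes near the transverse borders add grazing crossings.

The simple-shaped derivative replaces every border by the straight chord
between its junction points ("connecting the tricellular junctions").  This
preserves cell count, junction points, adjacency graph and total area exactly,
and never lengthens a perimeter.  `project_outlines_to_cylinder` accepts
externally supplied outline tilings (vertex-matched along shared borders,
seam-aware) and applies the same smoothing operator, whose endpoint-pinned
local averaging never increases total absolute boundary curvature.

## Membrane meshes

Cells are extruded inward to a depth of 2 µm (luminal radius = outer radius −
depth) and triangulated with a maximum triangle area of 4 µm² by default.  The
"4 µm" triangulation threshold is treated as an area (µm²); a length reading
would be dimensionally inconsistent with a triangle-area criterion.  Each cell
footprint is clipped by a structured grid whose pitch divides the period (so
grid crossings are identical on both sides of the seam), each clipped piece is
ear-clipped, and the footprint triangulation is instantiated on the outer
(abluminal) and inner (luminal) cylinder surfaces.  Lateral walls connect the
two boundary rings with no through-depth nodes, which keeps every node on a
curved surface and the membrane tangent nonsingular at the reference state.
Border vertices within 0.01 µm of a grid line are snapped onto it to prevent
sliver triangles.  Shared walls between adjacent cells reference one common
node set and carry both owner tags; every cell surface is a closed 2-manifold
(Euler characteristic 2), which the tests check per cell.

## Membrane finite elements and equilibrium

Three-node total-Lagrangian membrane elements carry a St. Venant–Kirchhoff
material reduced to plane stress,

    S = E/(1−ν²) [(1−ν) E_G + ν tr(E_G) I],

with `E_G` the in-plane Green–Lagrange strain and `S` the second
Piola–Kirchhoff stress — linear in strain, objective under large rotation.
Defaults: Young's modulus E = 100 kPa, membrane thickness t = 0.1 µm, so the
two membranes of a 2 µm-deep cell reproduce an effective cell-level modulus of
E·2t/depth = 10 kPa.  The Poisson ratio is not fixed by the idealization;
ν = 0.3 is the default and is an explicit parameter.  Stress is reported as
the trace of the in-plane second Piola–Kirchhoff tensor (kPa); projections
onto arbitrary directions (e.g. hoop) are available via `stress_component`.

Pressure acts as a follower load on deformed faces.  A uniform internal cell
pressure (default 0.015 kPa) loads all inside faces of each cell and cancels
exactly on shared walls, which carry both owners with opposite signs.  The
transmural case ("interstitial pressure exceeds lumen pressure by Δp") is
realized by assigning the extra pressure to the luminal faces — equivalently a
lumen pressure of −Δp (`LoadCase.transmural`).  Loading the abluminal surface
instead is possible through `abluminal_pressure` but is a mechanically
different construction (it squeezes the double-wall sandwich from outside
rather than loading the luminal membrane) and does not produce the same
ordering of templates.

Because all pressure loads here act on closed or fixed-boundary surfaces, they
are conservative with potential `p·V`; equilibrium is computed by minimizing
the total potential energy with a truncated-Newton method (Newton-CG on
diagonally scaled variables; the analytic assembled tangent, material +
geometric + follower-load parts, supplies Hessian-vector products).  This
choice is deliberate: membrane bulging and lumen collapse are post-buckling
phenomena — the unstressed membrane has near-inextensional soft modes and
load-controlled Newton continuation stalls on them, while energy minimization
follows the stable branch directly.  The residual (energy gradient) is exactly
the out-of-balance nodal force; convergence requires its max-norm below
`tol_rel` (default 1e-4) times the largest external nodal force.
Internal-force/energy consistency and the exactness of the tangent are checked
by finite differences in the tests; the solver is validated against the
thin-wall hoop-stress formula `σ = p·r/t` (mid-tube agreement to ~0.1% at the
test resolution, asserted at 5%).

Boundary conditions: both end node rings pinned by default (a one-end variant
is available).  Lumen metrics exclude 10 µm near each end to avoid the pinned
boundary layer.  Shared lateral walls are meshed once with the single default
membrane thickness (0.1 µm); whether the original model double-counted shared
walls is unknown, and the thickness is a parameter.

## Scenario summaries

`run_scenario` chains template → mesh → solve → summaries with full provenance
(seed and parameters recorded).  The lumen open-area profile is computed at 50
axial stations (fewer in the reduced test configuration): nearby luminal nodes
are binned by angle, the innermost radius per bin defines the open polygon,
and the area is normalized by the same construction on the reference mesh, so
the unloaded fraction is exactly 1.  "Cell-level" stress is the area-weighted
mean (and max) of element stress traces per cell, with shared walls
contributing to both owners; "tissue-level" is the area-weighted mean over all
elements.  `compare_templates` reports puzzle/simple stress ratios, the lumen
fraction difference, and the three qualitative flags (puzzle open, simple more
collapsed, puzzle lower stress).

With the default material and a 0.015 kPa cell pressure, the luminal faces
bulge several µm toward the axis (bulging is markedly stronger luminally than
abluminally), puzzle templates retain a larger minimal lumen fraction and a
lower tissue-level stress trace than their matched simple derivatives, and the
ordering persists across seeds and the transmural sweep Δp ∈ {0.005, 0.010,
0.015} kPa.  Mechanistically, lobed borders shorten the unsupported span of
each pressurized facet, and membrane bulge height and stress grow with facet
span.  These comparisons are asserted as strict orderings, not numeric
matches: no quantitative stress/lumen values are published for them.

Test and acceptance configurations run a reduced problem — 6 cells on a 45 µm
× 50 µm segment, 10 µm² triangle threshold, 25 stations with an 8 µm end
margin — chosen as the smallest geometry that still has interior cells and
several lobes per border; the full default (12 cells, 200 µm, 4 µm²) runs the
same code path.

## Quantification operators

**Overlap morphometry.**  The overlap of a mask pair is their raster
intersection; area is pixel count × pixel area.  Perpendicular width is
measured by transects: the longest geodesic path through the skeleton of each
overlap component is smoothed and resampled every 0.5 µm, the local mask
extent normal to the path tangent is sampled (0.25 px marching with a midpoint
boundary estimate), and samples within one local half-width of the path ends
are trimmed to remove end-cap artifacts.  The published measurement protocol
is not specified at this level of detail; the transect definition is the
package's operationalization of "perpendicular width" and is exact for
straight strips (a 3 × 10 µm rectangle strip measures 3.0 µm).  With a width
cap (4 µm in TEM-comparison mode) samples above the cap are excluded and
counted.  Width is undefined (flagged, never silently dropped) for disjoint
masks or overlaps too small to skeletonize.

**Junction linearity index**: contour length over endpoint chord length, ≥ 1.

**Junction classification.**  Five categories are called from a
`JunctionProfile` in fixed order: zipper (whole-cell adhesion coverage ≥ 0.9,
lobe marker absent), LYVE1⁻ curvilinear (lobe marker absent, a border covered),
button (lobe marker present, punctate neck deposit < 1.5 µm, both borders
uncovered), curvilinear (exactly one border covered), double (both covered);
anything else is explicitly unclassifiable and reported separately.  The
original annotation was by eye; `punctate_max = 1.5 µm`, `border_min = 0.3`
and `continuity_min = 0.9` are explicit, configurable stand-ins.  (The source
text says "four categories were defined" but enumerates five patterns; the
classifier implements the five-way rule set, and the thresholds object lets a
four-way variant be configured.)

**Lobe counting.**  Signed curvature is estimated on a Gaussian-smoothed
(σ = 1 µm arc length) resampling of the outline, positive = convex with
respect to the cell interior.  Lobes are maximal convex arcs separated by
concave arcs with arc length ≥ 2 µm and chord-normal amplitude ≥ 1 µm
(sub-micron wiggles are not lobes at the imaging scale); everywhere-convex
outlines have zero lobes.

**Microtubule anchoring.**  Endpoints are assigned to the curvature class of
the nearest smoothed-outline vertex within a 2 µm capture distance (rejections
tallied); fractions are over assigned endpoints and densities are endpoints
per µm of cortex arc length in each class.

## Synthetic-data generators

All generators are bit-reproducible functions of (config, seed), record their
ground truth, and exist so every estimator closes a generator–estimator loop.

*Overlap pairs*: width and area are drawn from zero-truncated normals at the
published summaries — control 2.3 ± 0.8 µm / 123.0 ± 52.6 µm² (n = 26),
fluid-injected 1.7 ± 0.7 / 83.4 ± 52.0 (n = 35), TEM 1.8 ± 0.9 µm (n = 34).
Truncation at zero adds a small positive bias (< 1% of the mean at these
coefficients of variation).  No joint width–area distribution is published;
they are drawn independently and coupled through the strip length `area /
width` (resampled with a tally when the implied strip is shorter than 5 µm or
longer than 250 µm, or the width below 3 pixels).  The TEM preset has no
published area, so strip length is drawn directly (50 ± 15 µm, truncated at
5 µm).  Masks are two cell bodies meeting along a gently sinusoidal interface
(amplitude 1 µm, wavelength 12 µm) sharing a band of constant perpendicular
width — the simplest geometry with a curved overlap strip; pixel size 0.1
µm/px.  What passing recovery tests show: the estimator is unbiased on
strip-like overlaps at confocal sampling.  What they do not show: performance
on convoluted TEM-style double-backed overlaps, segmentation error, or
intensity noise — inputs here are clean labeled masks by design.

*Junction profiles*: categories are drawn i.i.d. from the mixture (default:
20% button, 35% curvilinear, 25% double, 10% LYVE1⁻ curvilinear, 10% zipper —
only the button share is published; the remainder encodes "linear variants
most frequent" and is configurable), then archetype profiles satisfying each
rule with margin are jittered with coverage noise (σ = 0.05).  At zero noise
classification is exact by construction; at the default noise accuracy is
≈ 99% (the main confusion being zippers whose whole-cell coverage dips below
the continuity threshold).

*Lobed outlines*: rosettes `r = R(1 + a sin kθ)` with k drawn from a supplied
set; concave necks require `a k² > 1 − a`, which is validated.  *Microtubule
endpoints*: an exact `round(f·n)` split between curvature classes (default
f = 156/212 ≈ 0.736, the published endpoint counts), uniform within class,
with 0.3 µm positional jitter.

## Limitations

- The puzzle generator produces statistically lobate cells, not replicas of
  imaged outlines; only the "three cells per circumference" statement and
  qualitative lobe scale constrain it.
- Pure membrane elements: no bending stiffness, no self-contact resolution
  (self-intersecting lumen cross-sections are flagged and clipped at zero
  area), no viscoelasticity or active contractility.
- The mechanical comparison is qualitative by design; published outputs for it
  are images, not numbers.
- Mask-based metrics assume pre-segmented inputs; no raw-fluorescence
  processing is attempted.
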