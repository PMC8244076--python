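# Methods

cardiomesh implements the polygonal-surface-processing and mesh-generation
operations that a cardiac modelling pipeline chains together: connecting
segmentation surfaces, tagging anatomical regions, deriving mesh-size
fields from geometry, and post-processing volumetric meshes. This note
records the models, the numerical choices, and what the synthetic test
geometries do and do not establish.

## Data model and conventions

Surfaces are triangulated 2-manifolds with integer cell tags and named
point/cell fields; volume meshes are tetrahedral (or hexahedral after
conversion) with tagged boundary faces. All lengths are millimetres.
Indexing is 0-based. Closed surfaces are wound counter-clockwise seen
from outside (outward right-hand-rule normals); boundary rings are
ordered so that traversal keeps the surface on the left. Duplicate-point
merging uses a default tolerance of 1e-9 times the bounding-box
diagonal. VTK legacy ASCII is the canonical on-disk format because it
carries cell tags (`CELL_DATA SCALARS tag int`) and point fields;
STL/OBJ/PLY are untagged conveniences (STL is read as a triangle soup
and deduplicated exactly).

## Greedy band connection (zipper)

Two boundary rings with n1 and n2 points are joined by a triangle strip
built greedily: starting from a deterministic point on the first ring
(its lowest index; optionally randomized) and its closest point on the
second, each step appends the triangle whose connecting edge is shorter
of the two candidates, advancing on the first ring at ties. The band
always contains exactly n1 + n2 triangles and inserts n1 + n2 + 1
points (one start point is used twice); a dedicated closing triangle
seals the strip. Triangles are emitted so the band's winding is
compatible with coherently oriented parents; if the inputs' windings
are incompatible the band is flipped wholesale, and if neither
orientation fits a warning is raised (the surface is still watertight).
The step rule is deliberately simple: on smooth, roughly facing rings —
the valvular-annulus situation the operation exists for — it produces a
shape-following strip regardless of how different n1 and n2 are. On
adversarial inputs (wild radius jumps comparable to the gap) the greedy
walk can exhaust one ring before the other has advanced, which collapses
the closure; the randomized ring tests therefore use smooth low-order
Fourier perturbations of a circle (amplitude ≤ 0.15 R), which is also
what anatomical annuli look like.

## Boolean connection

Both closed inputs are cut at the zero level of their mutual signed
distances, the kept parts (per difference/union/intersection) are pulled
back by ε along the surface distance from the intersection curve (by
default ε = 2h; optionally only the first input is pulled back to keep a
sharp junction), remeshed at constant size h either everywhere or in a
3h-wide buffer, and rejoined with zipper bands, one per intersection
curve, paired by minimum average ring distance. Output tags: 1 = part
of the first input, 2 = part of the second, 3 = connection band. For
the difference the kept part of the second surface is orientation-
flipped so the result is a consistently outward-oriented closed surface.
Level-set cuts interpolate the field linearly along edges and
fan-triangulate the cut polygons; intersection points are shared per
edge, so the cut is watertight and the two sides stay conforming.

## Laplace–Beltrami solver

Piecewise-linear FEM with the cotangent stiffness matrix; Dirichlet
values are imposed by elimination and the reduced SPD system is solved
with a sparse LU; vector data is solved componentwise on one
factorization. Homogeneous Neumann is the natural condition on any
unconstrained boundary. Cotangent weights are not clamped on obtuse
triangles — clamping would change the operator — so the discrete
maximum principle is only guaranteed on non-obtuse meshes and is tested
there. Degenerate domains (minimum angle ≤ 1e-6 rad) are rejected with
the offending quality figure. On a developable cylinder the solver
reproduces the linear axial profile to machine precision (it lies in
the P1 space); the azimuthal m=1 mode excited by deforming a ring
radially decays as sinh((L−z)/R)/sinh(L/R), which is the closed form
the harmonic-connection test asserts.

## Harmonic connection and field extension

A surface is attached to a reference by rigidly registering one of its
boundary rings to a reference ring (centroid alignment, or ICP with
point-to-segment correspondences and a Kabsch fit with reflection
guard; ICP converges linearly, so tight recovery tolerances need more
than the default 50 iterations), prescribing the ring's closest-point
displacement as Dirichlet data, clamping excluded tags (and optionally
the free rings) to zero, solving the vector Laplace–Beltrami problem,
warping, clipping the deformed surface one band-width h away from the
reference ring, and zipper-connecting. Field extension follows the same
pattern for data instead of geometry: values on source tags become
Dirichlet data on the shared boundary, optional zero tags and free-ring
constants complete the boundary conditions, and the interior is filled
harmonically. Extended vector fields are not renormalized by default
(the operator is linear; unit length is not preserved by averaging); an
opt-in normalization flag serves direction fields such as myocardial
fibers.

## Tagging

The simple algorithm thresholds the field at cell barycenters (mean of
vertex values, consistent with P1 interpolation) and touches nothing
else; the clip algorithm splits triangles exactly at the level set; the
harmonic algorithm moves the zig-zag ring of the simple result onto the
clip polyline and blends the movement harmonically inside a buffer of
radius ρ (default 5 × mean edge length), keeping point and triangle
counts unchanged. Before warping, the zig-zag ring is pruned exactly as
specified by the consecutive-triangle rule — whenever three consecutive
ring points share a triangle one of them is dropped, the first only if
its predecessor survives — which is what prevents triangles from
collapsing to segments; triangle inversion after the warp raises an
error suggesting a larger ρ. The field is updated as f + |φ| only for
unsigned-distance-like fields; any other field requires a caller-
supplied recompute hook, otherwise the operation refuses to tag from
stale values. Connectivity tagging relabels edge-connected components
deterministically by lowest contained cell index. The explicit-cell
tagger replaces the paper-tool's interactive drawing; its geodesic seed
mode runs Dijkstra on the vertex graph augmented with the diagonals of
each edge's adjacent-triangle rhombus, which keeps the graph-metric
inflation within a few percent on smooth meshes.

## Thickness, thickening, mesh size

Wall thickness on the tagged walls is max(D_ext, D_int1) for a single
cavity and max(min(max(D_int1, D_int2), D_ext), D_int) when two
cavities share a septum, from exact unsigned distances between the
tagged sub-surfaces; off the tagged walls the value is projected from
the nearest tagged point (harmonic extension is the documented smoother
alternative). Thickening displaces points with τ below the target σ by
½·α·(σ−τ) along freshly recomputed angle-weighted vertex normals — the
½ because both walls move; α (default 1) is the user's correction for
the fact that a normal-direction warp under-delivers on curved walls,
and excluding one wall with α = 2 recovers σ from one side only.
Mesh-size terms map a field through clamp(α·f^β + γ) into [m, M] and
combine by pointwise minimum; the companion smoothed field is produced
by iterative 1-ring averaging (default 10 iterations, λ = 1), a convex
combination that preserves global bounds. Mean curvature is |Δx|/2 with
the cotangent operator and mixed Voronoi vertex areas, sign discarded.

## Remeshing

Incremental isotropic remeshing: split edges longer than 4/3 of the
local target, collapse those shorter than 4/5, flip toward valence 6
(4 on boundaries), relax tangentially and project back to the input
surface. Cells outside the target tags are never touched and their
vertices are frozen; edges on tag–tag interfaces and on the surface
boundary are constraints whose vertices only slide along the original
polyline, with corners (bends over 30°) and junctions pinned. Collapses
are guarded by the link condition and by normal/degeneracy checks and
rolled back when invalid.

## Volume operations

The tetrahedralization seam accepts any backend that preserves the
boundary triangulation; the built-in fallback cones all boundary
triangles to the centroid and is valid exactly for star-shaped regions
(it reports otherwise — a torus-like gap needs an external backend).
Mesh connection extracts the tagged boundary patches, pairs their rings
by minimum average distance, builds one zipper wall per pair (fresh tag
each), remeshes only the walls (patches frozen, hence conforming),
fills each closed component of the resulting connection surface, and
merges everything with exact-coordinate point deduplication, so the
input tets survive bit-identically and total volume is conserved to
rounding. Refinement is conforming longest-edge bisection toward
h(x) = max(m, α·f(x)^β): a tet is split while its longest edge exceeds
1.5·h at its barycenter, every tet sharing a split edge is split too,
and children inherit tags — identical, by construction, to projecting
tags from the input mesh by barycenter point-location. Tet-to-hex
splits each tet into 4 hexes through edge midpoints, face barycenters
and the cell barycenter (each boundary triangle into 3 quads); all six
faces of these hexes are planar, so the conversion conserves volume
exactly. RBS splits each hex into 8 through the trilinear midpoints;
sub-cell trilinear maps are restrictions of the parent map, so volume
is conserved in the trilinear sense, and the reported hex volume is the
exact integral of the trilinear Jacobian (2×2×2 Gauss, which is exact
at this polynomial degree).

## Synthetic geometries and their limits

All test geometries are generated deterministically in code: icospheres
and concentric shells (walls), a two-cavity shell (biventricular analog
with septum), open tubes and flat annuli (closed-form harmonic
solutions), star tubes with smooth Fourier rims (annulus analogs),
Kuhn-subdivided boxes (6n³ tets, exact volume), and a truncated prolate
ellipsoid — open, capped, or as a walled shell — as the idealized left
ventricle. These fixtures have exact reference values, which is what
makes the quantitative tests sharp; they are smooth and tag-clean,
unlike real segmentation output, so passing them demonstrates
correctness of the algorithms, not robustness to imaging noise,
self-intersections, or topological defects, which are out of scope.
Problem sizes in the tests and the acceptance script (subdivision
levels 3–4, tubes of a few thousand triangles, a 48-tet cube refined to
~7·10⁴ tets) are chosen so every reference value is resolved within its
stated tolerance while the whole suite runs in minutes on one core.
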