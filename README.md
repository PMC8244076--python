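# cardiomesh

Polygonal surface processing and mesh generation for cardiac model
building.

Patient-specific simulations of the heart — electrophysiology,
mechanics, hemodynamics — start from segmentation surfaces that are
rarely ready for volume meshing: the endocardium and epicardium come as
separate (often intersecting) closed surfaces, chambers are
reconstructed independently and separated by gaps, anatomical
boundaries such as the valvular annuli lie on smooth regions with no
sharp edges to detect, and wall thickness or trabecular detail varies
by an order of magnitude across the geometry. cardiomesh is a toolkit
of composable operations for exactly this preprocessing, aimed at
people building cardiac (or other biomedical) meshing pipelines in
Python.

What it provides:

* **Surface connection** — joining two boundary rings Γ₁, Γ₂ with a
  greedy band of exactly n₁+n₂ triangles, always adding the triangle
  with the shortest connecting edge (the primitive behind every other
  connection).
* **Boolean connection** — difference/union/intersection of closed
  surfaces via signed distances, with an ε-offset clip away from the
  intersection curve, local remeshing, and automatic tags for the two
  parts and the junction band (e.g. building a ventricular wall from
  epicardium and endocardium).
* **Harmonic connection and field extension** — solving Δφ = 0 on the
  surface (P1 cotangent FEM) to carry a boundary ring onto a reference
  ring, or to extend scalar/vector data (displacements, fiber
  directions) from a tagged subregion to the rest of the surface.
* **Tagging** — thresholding any per-point field f at a cut-off σ:
  per-cell (`simple`), by exact level-set splitting (`clip`), or by
  harmonically warping the mesh so the tag boundary is exact while the
  connectivity is untouched (`harmonic`); plus connectivity and
  explicit/geodesic cell tagging.
* **Thickness and thickening** — wall thickness τ from unsigned
  distances between tagged walls, max(D_ext, D_int1) with a septum-aware
  two-cavity variant, and thickening by ½α(σ−τ) along the normals where
  the wall is thinner than σ.
* **Mesh-size fields** — h(x) = clamp(α·f(x)^β + γ, [m, M]) per
  geometric quantity (curvature, thickness, distances), combined by
  pointwise minimum, with neighbourhood smoothing.
* **Remeshing** — isotropic incremental remeshing driven by h(x),
  restricted to chosen tags with frozen surroundings and preserved tag
  boundaries.
* **Volume operations** — connecting two tetrahedral meshes with a
  generated, conforming, tagged volumetric ring; sizing-driven
  conforming refinement with exact tag projection; tet→hex conversion
  (4 hexes per tet, 3 quads per boundary triangle) with
  refine-by-splitting.

Everything is available both as a library (`cardiomesh.*` modules) and
as a pipeline-composable CLI (`cardiomesh <stage> ...` with a YAML
`pipeline` runner). Deterministic synthetic cardiac-like geometries
(shells, two-cavity shells, tubes, truncated-ellipsoid ventricles) are
included for testing and experimentation.

## Worked example

Repair an unrealistically thin wall and derive its mesh size — here a
spherical shell of radii 4.75/5.25 mm standing in for a thin chamber
wall (tag 1 = outer, tag 2 = inner):

```python
from cardiomesh.synthetic_fixtures import shell
from cardiomesh.sizing_and_thickness import (
    SizingSpec, ThickenSpec, mean_curvature, mesh_size,
    surface_thickness, surface_thicken)

wall = shell(4.75, 5.25, level=3)
wall = surface_thickness(wall, internal_tags_1={2}, external_tags={1})
tau = wall.point_fields["thickness"]
print(f"wall thickness: {tau.mean():.3f} mm (min {tau.min():.3f})")

thick = surface_thicken(wall, ThickenSpec(sigma=1.0))
thick = surface_thickness(thick, {2}, {1})   # refresh tau on the new geometry
print(f"after thickening to sigma=1: "
      f"{thick.point_fields['thickness'].mean():.3f} mm")

sized = mean_curvature(thick)
sized = mesh_size(sized, [
    SizingSpec("curvature", alpha=0.3, beta=-0.5, m=0.3, M=2.0),
    SizingSpec("thickness", alpha=0.5, m=0.3, M=2.0),
])
h = sized.point_fields["h_smooth"]
print(f"mesh size h: {h.min():.3f} .. {h.max():.3f} mm")
```

prints

```
wall thickness: 0.499 mm (min 0.498)
after thickening to sigma=1: 0.999 mm
mesh size h: 0.499 .. 0.501 mm
```

The measured 0.5 mm wall is inflated to the 1 mm target (both walls
move by ¼ mm along their outward normals), and the combined sizing
field settles on 0.5·τ ≈ 0.5 mm — two elements per wall thickness —
because the thickness term is smaller than the curvature term
0.3·|c|^(−1/2) ≈ 0.67 mm everywhere on this smooth shell.

The same chain as a shell pipeline (thickness is recomputed after the
thickening so the sizing sees the repaired wall):

```bash
cardiomesh fixture --kind shell -p r_inner=4.75 -p r_outer=5.25 -p level=3 -o wall.vtk
cardiomesh thickness -i wall.vtk --inner1 2 --outer 1 -o wall.vtk
cardiomesh thicken   -i wall.vtk --sigma 1.0 -o wall.vtk
cardiomesh thickness -i wall.vtk --inner1 2 --outer 1 -o wall.vtk
cardiomesh meshsize  -i wall.vtk --curvature \
    --spec f=curvature,a=0.3,b=-0.5,m=0.3,M=2 \
    --spec f=thickness,a=0.5,m=0.3,M=2 -o wall.vtk
cardiomesh remesh    -i wall.vtk --size-field h_smooth --iters 5 -o wall_remeshed.vtk
```

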