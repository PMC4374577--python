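# Methods

## The registration model

Landmark-based non-rigid registration expresses the displacement field as
a radial basis function (RBF) transform: for each spatial component *j*,

    du_j(x) = P_j(x) + sum_i  lambda_ij * f( d(x, x_i) )

with `P_j` a first-order polynomial, `x_i` the N landmark centres and `f`
one of four radial bases — thin plate spline `r^2 log r`, multiquadric
`sqrt(r^2 + c^2)`, inverse multiquadric `1/sqrt(r^2 + c^2)`, or
Wendland's compactly supported `(1 - r/c)^4 (4 r/c + 1)` on `r <= c`.
The coefficients solve the block design system

    [ 0    X ] [ a      ]   [ 0 ]
    [ X^T  R ] [ lambda ] = [ D ]

whose zero block imposes `sum_i lambda_ij = 0` and
`sum_i lambda_ij x_i = 0`; the transform therefore reproduces affine
displacement data exactly with all `lambda = 0`, and interpolates the
landmark displacements exactly otherwise (no smoothing variant is
implemented).

The *constrained distance transform* (CDT) is this model with the distance
`d` taken not as the Euclidean norm but as the **geodesic distance inside a
simplicial mesh conforming to the object's domain**.  Distances between
regions then reflect connectivity along the object: the tip of a curled
tail may be 14 length units from the head through the background but 200
along the body, so a tail edit leaves the head still.  Displacements are
evaluated only at mesh nodes and interpolated barycentrically inside
elements, which both caps the cost of basis evaluation and makes the
transform trivially invertible element by element.  No bijectivity is
enforced: fold-overs (one-to-many) and fusions (many-to-one) are legal
outcomes and are resolved deterministically during resampling
(lowest/ascending element index).

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `kind` | radial basis | `imq` | stable, bounded response at long range |
| `delta` | shape scale, `c = delta * r_max` with `r_max` the maximum extent of the object (world units) | 0.05 | balances landmark fidelity against smoothness; useful range ~[0.001, 0.5], warned outside |
| `use_los` | line-of-sight initialisation of the geodesic solver | on | removes the point-source error entirely in the visible region |
| `constrained` | geodesic vs Euclidean distances | on | the point of the method; off gives the classical RBF warp for comparison |
| `interp` | value sampling | `linear` | `nearest` for label images |
| `target_edge` | mesh lattice step (world units) | — | controls node count; interpolation error scales as `N^(-1/3)` in 3D |

The multiquadric comparison warp in the locality study follows the same
configuration with `kind="mq"`.

## Geodesic distances on the mesh

Distances from a seed to all mesh nodes are computed in two stages.

**Stage 1 — nearest-neighbour line of sight.**  Every element whose
closure contains the seed is visible by convexity and is initialised
exactly.  An element queue, keyed by the candidate node's Euclidean
distance, then grows the visible region: a node passes when the ray from
it towards the seed crosses a facet of its element whose facet-opposite
element is already classified visible; passing nodes receive the exact
Euclidean norm.  The test is deliberately local and conservative: it never
marks an occluded node, but may miss visible ones (they are recovered by
stage 2 at slightly lower accuracy).  Two robustness refinements matter on
lattice meshes, where rays routinely pass exactly through mesh vertices:
a grazing hit at a facet vertex/edge is accepted when the grazed nodes are
themselves visible and some element incident to all of them is classified
visible; and an element all of whose vertex rays exit through vertices is
classified via the ray from its centroid.  Ray-facet intersection uses a
1e-9 relative tolerance.

**Stage 2 — mesh fast marching.**  A priority-queue front propagation in
causal (increasing-distance) order, ties broken by node index.  The local
update on a simplex solves the unit-speed plane-wave (eikonal) problem:
with known values `d_i` at nodes `x_i` and unknown node `C`, the quadratic
`|P^{-1}(d - dC 1)| = 1` (rows of `P` are `x_i - C`) is solved for the
larger root, accepted only if `dC >= max d_i` and the characteristic
direction lies inside the simplex.  Faces and edges of tetrahedra are
tried as lower-dimensional updates (projected into their affine span —
admissible overestimates), and the one-dimensional edge update
`d_i + |C - x_i|` is the final fallback, so candidates are always upper
bounds and the march terminates.  For obtuse configurations that violate
causality a *virtual node* is interpolated at the foot of the
perpendicular from the unknown node onto the known edge/face and the
update is performed on the split simplex.  Line-of-sight distances are
frozen — they are exact by construction.  Accepted values are finally
clamped from below by the Euclidean norm to the seed, a certified lower
bound of any geodesic; this removes a rare first-order undershoot in the
rarefaction fan behind concave corners and can only reduce error.

Seeds need not be nodes: a seed within 1e-6 of an element diameter of a
node snaps to it, otherwise the containing element's nodes are initialised
with exact Euclidean distances.

**Raster baselines.**  Morphological region growing under the mask with
4/8/octagonal structuring elements (6/26/octagonal in 3D); octagonal
alternates the full and face elements starting with the full one.
Distance is calibrated as iteration count times the (isotropic) cell
spacing.  These are the standard definitions of these metrics; they are
kept as accuracy/cost baselines only.

## Meshing

Meshes are generated on a Kuhn (Freudenthal) lattice: each lattice cell is
split into `dim!` simplices along its main diagonal, which is conforming
across cells by construction.  A simplex is kept when its centroid falls
in a foreground cell or when it contains a foreground cell center (the
latter guarantees coverage of the domain); nodes left outside the mask are
snapped to the nearest point of the nearest foreground cell — a point on
the mask surface — capped at one lattice edge and reverted where the move
would invert an incident element.  The centroid rule is kept tight (no
mask dilation) so that elements barely overhang the domain and geodesics
cannot cut through background near concave corners.  This lattice
generator was chosen over boundary-contour constrained Delaunay: it
guarantees conformity and coverage with deterministic output, at the cost
of element-shape optimality (right-angled simplices), which the obtuse
handling in the fast marcher absorbs.  High-quality external meshes can be
imported from Gmsh v2.2 ASCII, VTK legacy ASCII or OFF files; import
rejects mixed-element and non-simplicial meshes.

Orientation (positive signed volume) is enforced at construction by vertex
reordering; point location resolves boundary ties to the lowest element
index for determinism.

## Registration pipelines

For atlas mapping the mesh lives on the **target** (atlas) domain and
displacements map target space into source space (`D = source - target`
at the target centres).  Pull-back resampling then defines the warped
image exactly on the rasterised mesh footprint — foreground segmentation
is a by-product — and positions that leave the source raster are filled
and flagged unmapped, so absence of signal is always distinguishable from
unmapped territory.  One geodesic field is computed per landmark and
cached by centre, so interactively editing one landmark recomputes exactly
one field.  The centre-centre geodesic matrix is read off these fields
(barycentric interpolation when a centre is not a node) and symmetrised as
`(A + A^T)/2` before basis evaluation, since fast-marching approximation
breaks exact symmetry.  Coordinates are affinely rescaled to the unit box
before solving the design system (condition-number reduction) and the
system is solved by SVD with a relative cutoff of 1e-12, one factorisation
shared across the spatial components.

`forward_transform` covers the mesh-on-source direction: displaced
elements are rasterised one by one (per-simplex scanline), each covered
output cell inverts barycentrically to source coordinates and samples the
source; overlapping displaced elements resolve last-written-wins in
ascending element index, and degenerate (zero-volume) displaced elements
are skipped and counted.

## Synthetic fixtures and what they show

No external data is required; all evaluation inputs are generated:

- **Corridor domains** (L- and C/U-shaped unions of axis-aligned
  rectangles; 3D versions are prism extrusions).  Their geodesics have a
  closed form — the taut string through the inner corners — implemented as
  a tiny visibility graph with exact polygon predicates; for extrusions
  `sqrt(g2d^2 + dz^2)`.  The rectilinear geometry is deliberately aligned
  to the raster so the mask is the exact rasterisation of the polygon.
  These fixtures exercise non-convexity but not curved boundaries,
  anisotropic spacing or topological holes; accuracy numbers on them
  transfer to smooth anatomies only in order of magnitude.
- **Tail fixture**: a disc body with a thick arc tail hooking back so the
  tip ends ~14 units from the head surface but ~200 along the object;
  zero-displacement landmarks on the body silhouette and sparsely along
  the tail midline, two displaced tip landmarks.  The landmark layout is
  intentionally boundary-only and sparse — a dense protective ring around
  the head would let even the unconstrained warp keep the head still and
  mask the locality effect the fixture exists to demonstrate.
- **Pattern images** (checkerboard, coordinate ramp, component labels)
  for resampling audits.

**Distance-error study.**  Each algorithm's percentage error
`100 (computed - exact)/exact` against the analytic oracle, probed at all
mesh nodes (mesh algorithms) or mask cells (raster), seed excluded; mesh
nodes that sit marginally outside the oracle polygon (snapped boundary
nodes) are excluded from the probe set.  On the 2D corridor at ~1e4 nodes
the mesh algorithm's mean |error| is below 0.1%, line-of-sight
initialisation improves the mean error by an order of magnitude, and the
raster baselines are 10-100x worse — the orderings, not the exact factors,
are the reproducible content, since published error figures are tied to a
specific unavailable test geometry.

**Displacement-error study.**  For a fixed random landmark set (75
landmarks, displacements bounded by 10% of the domain extent, IMQ,
delta = 0.05) and a ladder of mesh resolutions, the RBF is evaluated
directly at every element centroid and compared with the barycentric
interpolation from the nodes; the primary statistic is the mean of
`eps = (l_RBF - l_MESH)/l_RBF` (the difference of displacement lengths
normalised by the direct length; the normalised error-vector length is
also reported).  The study uses **Euclidean** distance semantics: direct
evaluation at centroids requires landmark-to-centroid distances at
non-node points, which the constrained transform does not define
(constrained distances exist only at mesh nodes), and Euclidean semantics
make the direct evaluation exact so the statistic isolates the
piecewise-linear interpolation error that the study is about.  Mean eps
falls strictly with node count and correlates with `N^(-1/3)` at
r ~ 0.98 across meshes from ~8e3 to ~1e6 nodes
(`scripts/acceptance.py` recomputes this end to end; the test suite runs
the same study with the top resolution reduced to ~3e5 nodes to stay
within a single-CPU minute).

## Numerical choices and degenerate inputs

- All tolerances are relative where a natural scale exists: ray-facet
  intersection 1e-9 of element diameter, barycentric containment 1e-9,
  design-system SVD cutoff 1e-12, landmark coincidence 1e-9 of the
  centre-set extent.
- TPS at r = 0 uses the limit value 0 (removable singularity).
- The Wendland member used is the C^2, positive-definite-in-3D function
  `(1-r)^4(4r+1)`, argument scaled by `r/c`.
- Unbounded bases (TPS/MQ) raise on infinite node distances (disconnected
  mesh component); compact/decaying bases tolerate them.
- Empty domains, degenerate (single-row) domains, seeds/landmarks outside
  the mesh, non-simplicial mesh imports, and rank-deficient design
  systems (e.g. collinear centres with TPS) all raise typed errors naming
  the offending entity.
- Determinism: fixed inputs give bit-identical distance fields, warps and
  resampled images; heap ties break on node index, rasterisation
  conflicts on element index.

## Known limitations

- First-order fast marching: ~0.03-0.5% mean distance error at practical
  resolutions, concentrated behind concave corners; no second-order or
  exact polyhedral solver is provided.
- Lattice meshes trade element quality for robustness; no smoothing, edge
  flips or adaptive refinement.
- The raster baselines require isotropic spacing.
- Landmark-free (intensity-driven) registration, regularised/approximating
  splines, and fold-over penalties are out of scope.
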