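# cdt — constrained distance transforms for spatial atlas registration

Landmark-based non-rigid 2D/3D image registration in which the radial
basis function (RBF) displacement field is computed with **distances
constrained to geodesics inside a simplicial mesh conforming to the
object's domain**.  The package targets spatial atlas systems (e.g.
mapping gene-expression assay images of embryos onto a reference model),
where the required warps involve extreme pose variation — curled or
articulated tails whose tip is close to the head in Euclidean space but
far along the body.  Classical RBF warps drag everything that is near in
space; the constrained transform respects object connectivity, so large
pose corrections stay local to the part being moved, and registering onto
a pre-segmented atlas mesh segments the assay image from its background as
a by-product.

## The model

Displacements are interpolated from N landmark pairs per component *j*:

    du_j(x) = P_j(x) + sum_{i=1..N} lambda_ij f( d(x, x_i) )

with `P_j` a first-order polynomial and `f` a thin plate spline,
multiquadric (MQ), inverse multiquadric (IMQ) or Wendland basis with
shape parameter `c = delta * r_max` (`r_max` = maximum object extent,
default `delta = 0.05`, default basis IMQ).  Coefficients solve the block
design system `[[0, X], [X^T, R]] [a; lambda] = [0; D]` by SVD, with side
conditions `sum lambda = 0`, `sum lambda x = 0`.  In the *constrained*
transform every distance `d` entering `R` and the evaluation is a geodesic
inside the conforming mesh, computed by a two-stage solver: a
nearest-neighbour line-of-sight pass assigns exact Euclidean distances to
nodes visible from the seed, then mesh fast marching (with virtual-node
handling of obtuse simplices) propagates the front through the rest of the
mesh.  Displacements are evaluated at mesh nodes only and interpolated
barycentrically inside elements.  See `docs/methods.md` for the full
account.

## Worked example

Build a non-convex test domain with a known analytic geodesic, mesh it,
and compare the distance algorithms:

```sh
cdt fixtures corridor --dim 2 --outer 100,100 --width 20 --out corr.png
cdt mesh --in corr.png --edge 1.0 --out corr.msh
# -> mesh: 5481 nodes, 10400 elements -> corr.msh
cdt eval-distance --outer 100,100 --width 20 --edge 1.0 --out table.tsv
```

prints the error of each algorithm against the exact corridor geodesic
(percent, mean ± sd over all probe points):

```
algorithm   mean_percent_error   sd_percent_error
mesh             0.132742           0.160873
mesh_nlsi        0.699996           1.40359
c4              13.4709             8.25886
c8              -2.50621            4.39803
oct             -1.30893            2.39873
```

Reading: the mesh fast-marching distance (`mesh`) is accurate to ~0.1%;
dropping the line-of-sight initialisation (`mesh_nlsi`) costs a factor
~5; the raster region-growing baselines (`c4` city block, `c8`
chessboard, `oct` octagonal) carry their characteristic metrication
errors of 1-13%, city block over- and chessboard under-estimating.
Errors shrink further with mesh refinement (`--edge 0.72` gives ~0.03%
mean at ~1e4 nodes).

The same machinery registers an image in one call (here with landmark
pairs in `lm.tsv`, target coordinates then source coordinates per row):

```sh
cdt register --source assay.png --atlas-mask atlas.png --mesh atlas.msh \
             --landmarks lm.tsv --basis imq --delta 0.05 --out warped.png
# -> registered: 400 voxels mapped, 0 unmapped, max landmark residual 3.77e-15
```

The output support equals the atlas mesh footprint (registration ==
segmentation); the report JSON records residuals, unmapped-voxel count and
stage timings.  From Python, the same pipeline is
`cdt.register(source, atlas_domain, mesh, target_pts, source_pts,
RegistrationConfig())`, and the locality contrast of the method is two
lines: build the same warp with `constrained=True/False` and compare
nodal displacements far from the edited landmarks (see
`tests/test_acceptance.py::TestMeshDefinedLocality`).

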