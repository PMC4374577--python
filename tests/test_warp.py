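import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cdt.imagedomain import Domain, ImageObject
from cdt.mesh import generate_mesh_2d
from cdt.rbftransform import LandmarkSet
from cdt.geodesic import SeedError
from cdt.warp import (
    WarpField,
    RegistrationConfig,
    landmark_distance_fields,
    build_warp,
    pullback_resample,
    forward_transform,
    register,
)
from cdt.fixtures_eval import make_pattern_image, make_tail_fixture


@pytest.fixture(scope="module")
def square():
    dom = Domain(np.ones((24, 24), bool))
    mesh = generate_mesh_2d(dom, 4.0)
    img = make_pattern_image(dom, "checker", 4)
    return dom, mesh, img


class TestLandmarkDistanceFields:
    def test_single_landmark(self, square):
        _, mesh, _ = square
        fields, mat = landmark_distance_fields(mesh, [[10.0, 10.0]])
        assert len(fields) == 1 and mat.shape == (1, 1) and mat[0, 0] == 0.0

    def test_convex_pair_is_euclidean(self, square):
        # geodesic == Euclidean on the convex square, up to the linear
        # interpolation error of evaluating the field off-node
        _, mesh, _ = square
        centres = np.array([[4.0, 5.0], [18.0, 15.0]])
        _, mat = landmark_distance_fields(mesh, centres)
        eu = np.linalg.norm(centres[0] - centres[1])
        assert mat[0, 1] == pytest.approx(eu, rel=5e-3)
        assert mat[1, 0] == pytest.approx(eu, rel=5e-3)

    def test_cache_recomputes_only_edited_landmark(self, square):
        _, mesh, _ = square
        centres = np.array([[4.0, 5.0], [18.0, 15.0], [12.0, 8.0]])
        cache = {}
        fields1, _ = landmark_distance_fields(mesh, centres, cache=cache)
        edited = centres.copy()
        edited[1] = [17.0, 14.0]
        fields2, _ = landmark_distance_fields(mesh, edited, cache=cache)
        assert fields2[0] is fields1[0]  # untouched landmarks reuse the cache
        assert fields2[2] is fields1[2]
        assert fields2[1] is not fields1[1]

    def test_centre_outside_mesh_reports_index(self, square):
        _, mesh, _ = square
        with pytest.raises(SeedError, match="landmark 1"):
            landmark_distance_fields(mesh, [[5.0, 5.0], [99.0, 99.0]])


class TestBuildWarp:
    def test_zero_displacements_zero_field(self, square):
        _, mesh, _ = square
        X = np.array([[4.0, 4.0], [18.0, 4.0], [4.0, 18.0], [18.0, 18.0]])
        warp = build_warp(mesh, LandmarkSet(X, np.zeros((4, 2))),
                          RegistrationConfig())
        assert np.abs(warp.displacements).max() < 1e-9

    def test_translation_reproduced_at_all_nodes(self, square):
        _, mesh, _ = square
        X = np.array([[4.0, 4.0], [18.0, 4.0], [4.0, 18.0], [18.0, 18.0]])
        t = np.array([3.0, -2.0])
        warp = build_warp(mesh, LandmarkSet(X, np.tile(t, (4, 1))),
                          RegistrationConfig(kind="tps"))
        assert np.abs(warp.displacements - t).max() < 1e-6


class TestPullbackResample:
    def test_identity_restricts_to_footprint(self, square):
        dom, mesh, img = square
        warp = WarpField(mesh, np.zeros_like(mesh.nodes))
        out, unmapped = pullback_resample(img, warp, RegistrationConfig(), grid=dom)
        assert unmapped.sum() == 0
        m = out.domain.mask
        assert np.allclose(out.values[m], img.values[m])

    def test_translation_samples_shifted_source(self, square):
        dom, mesh, img = square
        t = np.array([4.0, 4.0])
        warp = WarpField(mesh, np.tile(t, (mesh.n_nodes, 1)))
        out, unmapped = pullback_resample(img, warp, RegistrationConfig(), grid=dom)
        ok = out.domain.mask & ~unmapped
        idx = np.argwhere(ok)
        src_idx = idx + 4
        keep = np.all(src_idx < 24, axis=1)
        a = out.values[tuple(idx[keep].T)]
        b = img.values[tuple(src_idx[keep].T)]
        assert np.allclose(a, b)

    def test_support_equals_footprint_for_any_content(self, square, rng):
        dom, mesh, _ = square
        noise = ImageObject(dom, rng.random(dom.shape) * 100)
        warp = WarpField(mesh, np.zeros_like(mesh.nodes))
        out1, _ = pullback_resample(noise, warp, RegistrationConfig(), grid=dom)
        ramp = make_pattern_image(dom, "ramp")
        out2, _ = pullback_resample(ramp, warp, RegistrationConfig(), grid=dom)
        assert np.array_equal(out1.domain.mask, out2.domain.mask)

    def test_values_within_source_range(self):
        fx = make_tail_fixture()
        cfg = RegistrationConfig(kind="imq")
        warp = build_warp(fx["mesh"], fx["landmarks"], cfg)
        out, unmapped = pullback_resample(fx["image"], warp, cfg,
                                          grid=fx["domain"])
        vals = out.values[out.domain.mask & ~unmapped]
        assert vals.min() >= fx["image"].values.min() - 1e-9
        assert vals.max() <= fx["image"].values.max() + 1e-9


class TestForwardTransform:
    def test_identity(self, square):
        dom, mesh, img = square
        warp = WarpField(mesh, np.zeros_like(mesh.nodes))
        out, ndeg = forward_transform(img, warp, RegistrationConfig())
        assert ndeg == 0
        # footprint area preserved
        assert out.domain.mask.sum() == pytest.approx(dom.mask.sum(), rel=0.05)

    def test_uniform_scaling_quadruples_area(self):
        nodes = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        from cdt.mesh import SimplicialMesh

        mesh = SimplicialMesh(nodes, np.array([[0, 1, 2], [0, 2, 3]]))
        dom = Domain(np.ones((11, 11), bool))
        img = make_pattern_image(dom, "ramp")
        warp = WarpField(mesh, nodes)  # u = 2x
        out, _ = forward_transform(img, warp, RegistrationConfig())
        assert out.domain.mask.sum() == pytest.approx(4 * 100, rel=0.15)

    def test_affine_round_trip(self, square):
        dom, mesh, _ = square
        img = make_pattern_image(dom, "ramp")  # smooth: interpolation-safe
        disp = 0.1 * mesh.nodes + np.array([1.0, 2.0])
        warp = WarpField(mesh, disp)
        cfg = RegistrationConfig()
        fwd, _ = forward_transform(img, warp, cfg)
        # pulling back through the same displacement field inverts the
        # forward transform (both send x to x + disp(x))
        back, unmapped = pullback_resample(fwd, warp, cfg, grid=dom)
        m = back.domain.mask & ~unmapped & dom.mask
        rng_v = np.ptp(img.values)
        diff = np.abs(back.values[m] - img.values[m])
        assert diff.mean() < 0.02 * rng_v


class TestRegister:
    def test_identity_pairs_restrict_source(self, square):
        dom, mesh, img = square
        pts = np.array([[4.0, 4.0], [18.0, 4.0], [4.0, 18.0], [18.0, 18.0]])
        out, report = register(img, dom, mesh, pts, pts, RegistrationConfig())
        assert report["landmark_residual_max"] < 1e-9
        m = out.domain.mask
        assert np.allclose(out.values[m], img.values[m])

    def test_bent_to_straight_corridor(self):
        """An L-bent corridor source registers onto a straight atlas with
        near-total coverage and exact landmark reproduction."""
        # straight atlas: horizontal bar
        mask_a = np.zeros((40, 40), bool)
        mask_a[14:26, 2:38] = True
        atlas = Domain(mask_a)
        mesh = generate_mesh_2d(atlas, 2.5)
        # bent source: an L shape
        mask_s = np.zeros((40, 40), bool)
        mask_s[14:26, 2:26] = True
        mask_s[14:38, 14:26] = True
        src = make_pattern_image(Domain(mask_s), "ramp")
        # landmarks: end corners, bend cross-section, far-end corners
        target = np.array([[15., 3.], [25., 3.], [20., 14.], [20., 20.],
                           [15., 20.], [25., 20.], [20., 28.],
                           [15., 36.5], [25., 36.5]])
        source = np.array([[15., 3.], [25., 3.], [20., 14.], [20., 20.],
                           [15., 20.], [25., 20.], [28., 20.],
                           [36.5, 15.], [36.5, 25.]])
        out, report = register(src, atlas, mesh, target, source,
                               RegistrationConfig(kind="tps"))
        assert report["landmark_residual_max"] < 1e-6
        mapped_frac = report["mapped_voxels"] / out.domain.mask.sum()
        assert mapped_frac >= 0.99

    def test_many_to_one_fusion(self):
        """Two disjoint source blobs both map into one atlas region."""
        mask_s = np.zeros((30, 30), bool)
        mask_s[4:12, 4:12] = True
        mask_s[18:26, 18:26] = True
        src = make_pattern_image(Domain(mask_s), "labels")
        atlas = Domain(np.ones((12, 12), bool))
        mesh = generate_mesh_2d(atlas, 3.0)
        target = np.array([[2.0, 2.0], [2.0, 9.0], [9.0, 2.0], [9.0, 9.0]])
        source = np.array([[5.0, 5.0], [5.0, 10.0], [20.0, 19.0], [24.0, 24.0]])
        out, report = register(src, atlas, mesh, target, source,
                               RegistrationConfig(kind="tps", interp="nearest"))
        vals = set(np.unique(out.values[out.domain.mask]))
        assert {1.0, 2.0} <= vals  # both blobs contribute

    def test_landmark_outside_atlas_mesh_reported(self, square):
        dom, mesh, img = square
        pts = np.array([[4.0, 4.0], [18.0, 4.0], [4.0, 18.0], [99.0, 99.0]])
        with pytest.raises(SeedError, match="landmark 3"):
            register(img, dom, mesh, pts, pts, RegistrationConfig())


class TestLocality:
    def test_constrained_warp_keeps_head_still(self):
        """Tail-tip displacement leaves the head untouched under the
        constrained warp but drags it under the unconstrained one."""
        fx = make_tail_fixture()
        mesh, lms = fx["mesh"], fx["landmarks"]
        mag = np.linalg.norm(fx["tip_displacement"])
        head = fx["head_nodes"]
        out = {}
        for constrained in (True, False):
            cfg = RegistrationConfig(kind="mq", constrained=constrained)
            warp = build_warp(mesh, lms, cfg)
            out[constrained] = np.linalg.norm(warp.displacements[head], axis=1).mean()
        assert out[True] < 0.01 * mag
        assert out[False] > 10 * out[True]

    def test_displacement_decays_with_geodesic_distance(self):
        """Under the constrained warp the response to the tip edit decays
        along the object."""
        fx = make_tail_fixture()
        from cdt.geodesic import geodesic_field

        warp = build_warp(fx["mesh"], fx["landmarks"],
                          RegistrationConfig(kind="imq"))
        field = geodesic_field(fx["mesh"], fx["tip"])
        mags = np.linalg.norm(warp.displacements, axis=1)
        near = field.distance < 30
        far = field.distance > 150
        assert mags[near].mean() > 10 * mags[far].mean()
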