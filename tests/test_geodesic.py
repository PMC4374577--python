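import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as sp_dijkstra

from cdt.imagedomain import Domain, DomainError
from cdt.geodesic import (
    local_update,
    line_of_sight_init,
    fast_march,
    geodesic_field,
    raster_geodesic,
    error_stats,
    SeedError,
    KNOWN_LOS,
)
from cdt.mesh import SimplicialMesh


def edge_graph_dijkstra(mesh, seed_node):
    """Shortest path over the mesh edge graph: an admissible geodesic
    approximant that always overestimates the continuous geodesic."""
    e = mesh.edges()
    w = np.linalg.norm(mesh.nodes[e[:, 0]] - mesh.nodes[e[:, 1]], axis=1)
    n = mesh.n_nodes
    g = coo_matrix((np.concatenate([w, w]),
                    (np.concatenate([e[:, 0], e[:, 1]]),
                     np.concatenate([e[:, 1], e[:, 0]]))), shape=(n, n))
    return sp_dijkstra(g.tocsr(), indices=seed_node)


class TestLocalUpdate:
    def test_equilateral_apex_is_height(self):
        coords = [[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]]
        cand = local_update(coords, [0.0, 0.0])
        assert cand == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_one_dimensional_fallback(self):
        # right triangle, only the node across the leg of length 3 known
        coords = [[0.0, 3.0], [0.0, 0.0]]
        cand = local_update(coords, [0.0])
        assert cand == pytest.approx(3.0, abs=1e-12)

    def test_plane_wave_matches_linear_field(self, rng):
        """On acute triangles carrying an exact linear unit-slope field the
        two-point update reproduces the analytic value."""
        checked = 0
        for _ in range(4000):
            if checked >= 25:
                break
            tri = rng.random((3, 2)) * 10
            a, b, c = tri
            # require all angles acute
            def ang(p, q, r):
                v1, v2 = q - p, r - p
                return np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2)
            if min(ang(a, b, c), ang(b, c, a), ang(c, a, b)) <= 0.05:
                continue
            g = rng.normal(size=2)
            g /= np.linalg.norm(g)
            d = tri @ g + 100.0  # plane wave distances, offset keeps them positive
            cand = local_update([a, b, c], [d[0], d[1]])
            # accept only if the characteristic points into the triangle,
            # otherwise the update legitimately exceeds the linear value
            assert cand >= d[2] - 1e-9
            if cand < d[2] + 1e-6:
                checked += 1
        assert checked >= 25

    def test_requires_known_neighbor(self):
        with pytest.raises(ValueError):
            local_update([[0.0, 0.0]], [])


class TestLineOfSight:
    def test_convex_disc_all_nodes_exact(self, disc_mesh):
        _, mesh = disc_mesh
        seed = np.array([18.3, 21.1])
        field = line_of_sight_init(mesh, seed)
        marked = field.state == KNOWN_LOS
        assert marked.all()
        eu = np.linalg.norm(mesh.nodes - seed, axis=1)
        assert np.abs(field.distance - eu).max() < 1e-12 * (1 + eu.max())

    def test_occluded_node_not_marked(self, corridor2d):
        mesh, seed = corridor2d["mesh"], corridor2d["seed"]
        oracle = corridor2d["oracle"]
        field = line_of_sight_init(mesh, seed)
        marked = field.state == KNOWN_LOS
        vis = oracle._visible(seed, mesh.nodes)
        # around-the-bend nodes exist and none of them is marked
        assert (~vis).sum() > 0
        assert not (marked & ~vis).any()

    def test_marked_subset_of_sampled_visibility(self, corridor2d):
        mesh, seed, dom = corridor2d["mesh"], corridor2d["seed"], corridor2d["domain"]
        field = line_of_sight_init(mesh, seed)
        marked = np.flatnonzero(field.state == KNOWN_LOS)
        from scipy import ndimage

        dil = ndimage.binary_dilation(dom.mask)
        shape = np.array(dom.shape)
        for n in marked:
            t = np.linspace(0, 1, 80)[:, None]
            pts = seed + t * (mesh.nodes[n] - seed)
            idx = np.clip(
                np.rint(dom.index_of_world(pts)).astype(int), 0, shape - 1
            )
            assert dil[tuple(idx.T)].all()

    def test_seed_outside_raises(self, corridor2d):
        with pytest.raises(SeedError):
            line_of_sight_init(corridor2d["mesh"], (30.0, 30.0))


class TestFastMarch:
    def test_straight_strip_length(self):
        # thin triangulated strip of 20 elements, length 10
        xs = np.linspace(0, 10, 11)
        nodes = np.array([[x, y] for x in xs for y in (0.0, 0.5)])
        elements = []
        for i in range(10):
            a, b, c, d = 2 * i, 2 * i + 1, 2 * i + 2, 2 * i + 3
            elements += [[a, b, c], [b, d, c]]
        mesh = SimplicialMesh(nodes, np.array(elements))
        field = geodesic_field(mesh, (0.0, 0.0), use_los=False)
        end = np.flatnonzero(np.all(mesh.nodes == [10.0, 0.0], axis=1))[0]
        assert field.distance[end] == pytest.approx(10.0, rel=0.005)

    def test_convex_square_from_corner(self):
        dom = Domain(np.ones((30, 30), bool))
        from cdt.mesh import generate_mesh_2d

        errs = []
        for h in (2.0, 1.0):
            mesh = generate_mesh_2d(dom, h)
            field = geodesic_field(mesh, (0.0, 0.0), use_los=False)
            eu = np.linalg.norm(mesh.nodes, axis=1)
            keep = eu > 1e-9
            errs.append(np.abs(field.distance[keep] - eu[keep]) / eu[keep])
            # the LOS path is exact on a convex mesh
            f_los = geodesic_field(mesh, (0.0, 0.0), use_los=True)
            assert np.abs(f_los.distance[keep] - eu[keep]).max() < 1e-6 * eu.max()
        # without LOS the error is refinement-limited: it shrinks with h and
        # is concentrated at the point-source singularity (median is small)
        assert errs[1].mean() < errs[0].mean()
        assert np.median(errs[1]) < 0.02

    def test_corridor_against_analytic(self, corridor2d):
        mesh, seed, oracle = corridor2d["mesh"], corridor2d["seed"], corridor2d["oracle"]
        field = geodesic_field(mesh, seed, use_los=True)
        inside = oracle.contains(mesh.nodes)
        exact = np.full(mesh.n_nodes, np.nan)
        exact[inside] = oracle.distances(seed, mesh.nodes[inside])
        keep = exact > 1e-9
        rel = np.abs(field.distance[keep] - exact[keep]) / exact[keep]
        assert rel.mean() < 0.005
        assert rel.max() < 0.02

    def test_los_never_increases_error(self, corridor2d):
        mesh, seed, oracle = corridor2d["mesh"], corridor2d["seed"], corridor2d["oracle"]
        inside = oracle.contains(mesh.nodes)
        exact = np.full(mesh.n_nodes, np.nan)
        exact[inside] = oracle.distances(seed, mesh.nodes[inside])
        keep = exact > 1e-9
        out = {}
        for use_los in (True, False):
            f = geodesic_field(mesh, seed, use_los=use_los)
            out[use_los] = np.abs(
                100 * (f.distance[keep] - exact[keep]) / exact[keep]
            ).mean()
        assert out[True] <= out[False]

    def test_disconnected_component_unreached(self):
        nodes = np.array([[0.0, 0], [1, 0], [0, 1], [5, 5], [6, 5], [5, 6]])
        elements = np.array([[0, 1, 2], [3, 4, 5]])
        mesh = SimplicialMesh(nodes, elements)
        field = geodesic_field(mesh, (0.2, 0.2), use_los=False)
        assert np.isinf(field.distance[3:]).all()
        assert np.isfinite(field.distance[:3]).all()

    def test_known_los_frozen_and_monotone_lower_bound(self, corridor2d):
        mesh, seed = corridor2d["mesh"], corridor2d["seed"]
        los = line_of_sight_init(mesh, seed)
        los_dist = los.distance.copy()
        los_nodes = los.state == KNOWN_LOS
        field = fast_march(los)
        assert np.array_equal(field.distance[los_nodes], los_dist[los_nodes])
        eu = np.linalg.norm(mesh.nodes - seed, axis=1)
        assert np.all(field.distance >= eu - 1e-9)

    def test_determinism(self, corridor2d):
        mesh, seed = corridor2d["mesh"], corridor2d["seed"]
        f1 = geodesic_field(mesh, seed)
        f2 = geodesic_field(mesh, seed)
        assert np.array_equal(f1.distance, f2.distance)
        assert np.array_equal(f1.state, f2.state)


class TestDijkstraBracketing:
    @pytest.mark.parametrize("fixture", ["corridor2d", "corridor3d"])
    def test_fmm_below_edge_graph(self, fixture, request):
        fx = request.getfixturevalue(fixture)
        mesh = fx["mesh"]
        seed_node = 0
        field = geodesic_field(mesh, mesh.nodes[seed_node], use_los=True)
        dj = edge_graph_dijkstra(mesh, seed_node)
        eu = np.linalg.norm(mesh.nodes - mesh.nodes[seed_node], axis=1)
        finite = np.isfinite(dj)
        assert np.all(field.distance[finite] <= dj[finite] + 1e-9)
        assert np.all(field.distance[finite] >= eu[finite] - 1e-9)
        assert np.all(dj[finite] >= eu[finite] - 1e-9)


class TestRasterGeodesic:
    def test_corridor_1d_chain(self):
        mask = np.zeros((1, 10), bool)
        mask[0] = True
        dom = Domain(np.vstack([mask, np.zeros_like(mask)]))
        dist = raster_geodesic(dom, (0, 0), "c4")
        assert np.allclose(dist[0], np.arange(10))

    def test_chessboard_metric(self):
        dom = Domain(np.ones((10, 10), bool))
        dist = raster_geodesic(dom, (0, 0), "c8")
        assert dist[9, 9] == 9.0

    def test_corridor_error_bounds(self, corridor2d):
        dom, oracle = corridor2d["domain"], corridor2d["oracle"]
        sidx = tuple(int(round(v)) for v in dom.index_of_world(corridor2d["seed"]))
        cells = np.argwhere(dom.mask)
        centers = dom.world_of_index(cells)
        exact = oracle.distances(dom.world_of_index(np.array(sidx)), centers)
        keep = exact > 1e-9
        errs = {}
        for conn in ("c8", "oct"):
            dist = raster_geodesic(dom, sidx, conn)[tuple(cells.T)]
            # chessboard-family metrics can undershoot by at most ~30%
            assert np.all(dist[keep] >= 0.7 * exact[keep])
            errs[conn] = np.abs(100 * (dist[keep] - exact[keep]) / exact[keep]).mean()
        assert errs["oct"] <= errs["c8"]

    def test_seed_outside_mask(self, corridor2d):
        with pytest.raises(SeedError):
            raster_geodesic(corridor2d["domain"], (30, 30), "c4")


class TestErrorStatsProperties:
    from hypothesis import given, settings, strategies as st

    @given(
        exact=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=30),
        scale=st.floats(0.5, 2.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_uniform_scaling_gives_constant_error(self, exact, scale):
        exact = np.asarray(exact)
        mean, sd = error_stats(scale * exact, exact)
        assert mean == pytest.approx(100 * (scale - 1), rel=1e-9, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-7)


class TestErrorStats:
    def test_exact_gives_zero(self):
        assert error_stats([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_uniform_one_percent(self):
        mean, sd = error_stats(np.array([1.01, 2.02]), np.array([1.0, 2.0]))
        assert mean == pytest.approx(1.0) and sd == pytest.approx(0.0, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            error_stats([], [])
        with pytest.raises(ValueError):
            error_stats([1.0], [0.0])
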