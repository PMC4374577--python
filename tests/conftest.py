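import numpy as np
import pytest

from cdt.imagedomain import Domain
from cdt.mesh import generate_mesh_2d, generate_mesh_3d
from cdt.fixtures_eval import CorridorDomainSpec, make_corridor_domain


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def corridor2d():
    """Small 2D C-shaped corridor with its analytic oracle and a mesh."""
    spec = CorridorDomainSpec(dim=2, outer=(60.0, 60.0), width=15.0, shape="c")
    dom, oracle = make_corridor_domain(spec)
    mesh = generate_mesh_2d(dom, 1.5)
    return {"spec": spec, "domain": dom, "oracle": oracle, "mesh": mesh,
            "seed": np.array([7.5, 7.5])}


@pytest.fixture(scope="session")
def corridor3d():
    """Small 3D extruded corridor with oracle and tetrahedral mesh."""
    spec = CorridorDomainSpec(dim=3, outer=(40.0, 40.0), width=12.0, shape="c",
                              depth=20.0)
    dom, oracle = make_corridor_domain(spec)
    mesh = generate_mesh_3d(dom, 3.0)
    return {"spec": spec, "domain": dom, "oracle": oracle, "mesh": mesh,
            "seed": np.array([6.0, 6.0, 10.0])}


def polar_disc_mesh(radius=18.0, center=(20.0, 20.0), n_rings=8, n_sectors=24):
    """Truly convex fixture: fan + ring triangulation of a regular polygon
    disc (its footprint is a convex polygon, so geodesic == Euclidean)."""
    from cdt.mesh import SimplicialMesh

    center = np.asarray(center)
    nodes = [center]
    for r in range(1, n_rings + 1):
        rad = radius * r / n_rings
        ang = 2 * np.pi * np.arange(n_sectors) / n_sectors
        nodes.extend(center + rad * np.stack([np.cos(ang), np.sin(ang)], axis=1))
    nodes = np.asarray(nodes)
    elements = []
    for s in range(n_sectors):
        elements.append([0, 1 + s, 1 + (s + 1) % n_sectors])
    for r in range(1, n_rings):
        a0 = 1 + (r - 1) * n_sectors
        b0 = 1 + r * n_sectors
        for s in range(n_sectors):
            s1 = (s + 1) % n_sectors
            elements.append([a0 + s, b0 + s, b0 + s1])
            elements.append([a0 + s, b0 + s1, a0 + s1])
    return SimplicialMesh(nodes, np.asarray(elements))


@pytest.fixture(scope="session")
def disc_mesh():
    """Convex fixture: polar disc mesh plus the raster domain it covers."""
    n = 40
    c = np.arange(n) + 0.5
    X0, X1 = np.meshgrid(c, c, indexing="ij")
    mask = (X0 - 20.0) ** 2 + (X1 - 20.0) ** 2 <= 18.0 ** 2
    dom = Domain(mask, origin=(0.5, 0.5))
    return dom, polar_disc_mesh()
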