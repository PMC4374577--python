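"""Simplicial conforming meshes over image domains.

Meshes (triangles in 2D, tetrahedra in 3D) conform to an object's domain:
their elements tile the foreground region so that connectivity — and hence
geodesic distance — follows the object's shape rather than the embedding
space.  Generation uses a Kuhn (Freudenthal) lattice subdivision clipped to
the mask: every lattice cell is split into ``dim!`` simplices along its
main diagonal, which is conforming across cells by construction; simplices
are kept when their centroid lies in a one-cell dilation of the mask or
when they contain a foreground cell center, and boundary nodes left
outside the mask are snapped onto it (capped at one lattice edge).  The
lattice strategy trades element-shape optimality for guaranteed
conformity, deterministic output and full coverage of the foreground.

External meshes (e.g. from a high-quality tetrahedralizer) can be imported
from Gmsh v2.2 ASCII, VTK legacy ASCII or OFF files.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imagedomain import Domain, DomainError, bounding_box

__all__ = [
    "SimplicialMesh",
    "MeshError",
    "generate_mesh_2d",
    "generate_mesh_3d",
    "import_mesh",
    "export_mesh",
]


class MeshError(ValueError):
    """Raised for invalid, non-conforming or unsupported meshes."""


class SimplicialMesh:
    """Nodes plus (dim+1)-node simplices with facet adjacency.

    Invariants: positive signed volume per element (enforced at
    construction by vertex reordering) and conformity (every facet shared
    by at most two elements; checked when adjacency is built).
    """

    def __init__(self, nodes, elements):
        self.nodes = np.ascontiguousarray(nodes, dtype=np.float64)
        self.elements = np.ascontiguousarray(elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] not in (2, 3):
            raise MeshError("nodes must be (n, 2) or (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != self.dim + 1:
            raise MeshError(
                f"elements must have {self.dim + 1} nodes each for dim {self.dim}"
            )
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise MeshError("element node index out of range")
        self._orient()
        self._neighbors = None
        self._node_star = None
        self._bbox = None

    # -------------------------------------------------------- basics ----

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_volumes(self) -> np.ndarray:
        """Signed area (2D) / volume (3D) per element."""
        pts = self.nodes[self.elements]
        mats = pts[:, 1:, :] - pts[:, :1, :]
        det = np.linalg.det(mats)
        fact = 2.0 if self.dim == 2 else 6.0
        return det / fact

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def _orient(self):
        vol = self.element_volumes()
        if np.any(vol == 0):
            raise MeshError("degenerate (zero-volume) element at construction")
        flip = vol < 0
        if flip.any():
            cols = self.elements[flip][:, [-1, -2]]
            self.elements[np.where(flip)[0], -2:] = cols

    def edges(self):
        """Unique undirected edges (k, 2) of the element graph."""
        d1 = self.dim + 1
        pairs = list(itertools.combinations(range(d1), 2))
        e = np.concatenate([self.elements[:, p] for p in pairs], axis=0)
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)

    # ----------------------------------------------------- adjacency ----

    def _facet_table(self):
        """(n_el*(d+1), d) sorted facet node sets; row i*(d+1)+l is the
        facet opposite local node l of element i."""
        d1 = self.dim + 1
        facets = np.empty((self.n_elements * d1, self.dim), dtype=np.int64)
        for l in range(d1):
            keep = [c for c in range(d1) if c != l]
            facets[l::d1] = self.elements[:, keep]
        facets.sort(axis=1)
        return facets

    @property
    def neighbors(self) -> np.ndarray:
        """(n_el, dim+1) facet-opposite element indices, -1 at boundary."""
        if self._neighbors is None:
            d1 = self.dim + 1
            facets = self._facet_table()
            order = np.lexsort(facets.T[::-1])
            srt = facets[order]
            same = np.all(srt[1:] == srt[:-1], axis=1)
            runs = np.flatnonzero(same)
            if runs.size >= 2 and np.any(np.diff(runs) == 1):
                raise MeshError("non-conforming mesh: facet shared by >2 elements")
            nb = np.full(self.n_elements * d1, -1, dtype=np.int64)
            a, b = order[runs], order[runs + 1]
            nb[a] = b // d1
            nb[b] = a // d1
            self._neighbors = nb.reshape(self.n_elements, d1)
        return self._neighbors

    def element_neighbors(self, e: int) -> np.ndarray:
        if not 0 <= e < self.n_elements:
            raise IndexError(f"element index {e} out of range")
        return self.neighbors[e]

    def node_star(self, n: int):
        """Indices of elements incident to node ``n``."""
        if not 0 <= n < self.n_nodes:
            raise IndexError(f"node index {n} out of range")
        return self.node_stars[n]

    @property
    def node_stars(self):
        if self._node_star is None:
            d1 = self.dim + 1
            flat = self.elements.ravel()
            order = np.argsort(flat, kind="stable")
            elems = order // d1
            counts = np.bincount(flat, minlength=self.n_nodes)
            splits = np.cumsum(counts)[:-1]
            self._node_star = np.split(elems, splits)
        return self._node_star

    def audit(self):
        """Raise MeshError unless orientation and conformity invariants hold."""
        if np.any(self.element_volumes() <= 0):
            raise MeshError("element with non-positive volume")
        _ = self.neighbors  # raises on facet shared by >2 elements
        # symmetry of the neighbor relation
        for e in range(self.n_elements):
            for nb in self.neighbors[e]:
                if nb >= 0 and e not in self.neighbors[nb]:
                    raise MeshError(f"asymmetric neighbor relation {e}<->{nb}")
        return True

    # ------------------------------------------------ point location ----

    def _bboxes(self):
        if self._bbox is None:
            pts = self.nodes[self.elements]
            self._bbox = (pts.min(axis=1), pts.max(axis=1))
        return self._bbox

    def barycentric(self, e: int, p) -> np.ndarray:
        """Barycentric coordinates of world point ``p`` in element ``e``."""
        verts = self.nodes[self.elements[e]]
        T = (verts[1:] - verts[0]).T
        rest = np.linalg.solve(T, np.asarray(p, float) - verts[0])
        return np.concatenate([[1.0 - rest.sum()], rest])

    def locate_point(self, p, tol: float = 1e-9):
        """Element containing ``p`` and its barycentric coordinates.

        Boundary points resolve to the lowest element index; returns None
        when ``p`` is outside the mesh.
        """
        p = np.asarray(p, dtype=float)
        lo, hi = self._bboxes()
        cand = np.flatnonzero(np.all((p >= lo - tol) & (p <= hi + tol), axis=1))
        for e in cand:  # ascending order = lowest-index tie-break
            b = self.barycentric(int(e), p)
            if np.all(b >= -tol):
                return int(e), b
        return None

    def interpolate(self, nodal, pts, outside=np.nan):
        """Barycentric interpolation of per-node data at world points."""
        pts = np.atleast_2d(np.asarray(pts, float))
        nodal = np.asarray(nodal, float)
        out_shape = (len(pts),) + nodal.shape[1:]
        out = np.full(out_shape, outside, dtype=float)
        for i, p in enumerate(pts):
            hit = self.locate_point(p)
            if hit is not None:
                e, b = hit
                out[i] = b @ nodal[self.elements[e]]
        return out


# ------------------------------------------------------------ generation --

def _kuhn_perms(dim):
    """Vertex offset patterns of the Kuhn subdivision: for permutation
    ``pi`` the simplex vertices are 0, e_pi0, e_pi0+e_pi1, ..."""
    perms = list(itertools.permutations(range(dim)))
    offs = np.zeros((len(perms), dim + 1, dim), dtype=np.int64)
    for k, pi in enumerate(perms):
        acc = np.zeros(dim, dtype=np.int64)
        for v, ax in enumerate(pi):
            acc = acc.copy()
            acc[ax] = 1
            offs[k, v + 1] = acc
    return perms, offs


def _perm_index_of_local(perms, u):
    """Which Kuhn simplex the local coordinates ``u`` (k, dim) fall in:
    the simplex of the permutation sorting u in descending order."""
    order = np.argsort(-u, axis=1, kind="stable")
    lut = {pi: k for k, pi in enumerate(perms)}
    return np.array([lut[tuple(row)] for row in order], dtype=np.int64)


def _generate_lattice_mesh(domain: Domain, target_edge: float, snap: bool = True):
    if domain.is_empty():
        raise DomainError("cannot mesh an empty domain")
    dim = domain.dim
    idx = np.argwhere(domain.mask)
    if np.any(idx.max(axis=0) == idx.min(axis=0)):
        raise DomainError("degenerate domain (single row/column/slice)")
    spacing = np.asarray(domain.spacing)
    origin = np.asarray(domain.origin)
    lo = origin - 0.5 * spacing
    hi = origin + (np.asarray(domain.shape) - 0.5) * spacing
    ncell = np.maximum(1, np.rint((hi - lo) / target_edge)).astype(int)
    step = (hi - lo) / ncell

    perms, offs = _kuhn_perms(dim)
    nperm = len(perms)
    grid = np.stack(
        np.meshgrid(*[np.arange(n) for n in ncell], indexing="ij"), axis=-1
    ).reshape(-1, dim)
    ncells_total = len(grid)

    # keep rule 1: simplex centroid inside a foreground cell (kept tight so
    # that elements barely overhang the domain and geodesics cannot cut
    # through background near concave corners)
    cent_local = offs.mean(axis=1)  # (nperm, dim)
    keep = np.zeros((ncells_total, nperm), dtype=bool)
    dil = domain.mask
    for k in range(nperm):
        cw = lo + (grid + cent_local[k]) * step
        ci = np.rint((cw - origin) / spacing).astype(int)
        ok = np.all((ci >= 0) & (ci < np.array(domain.shape)), axis=1)
        kk = np.zeros(ncells_total, dtype=bool)
        kk[ok] = dil[tuple(ci[ok].T)]
        keep[:, k] = kk

    # keep rule 2: simplex contains a foreground cell center (coverage)
    centers = domain.world_of_index(idx)
    f = (centers - lo) / step
    cell = np.minimum(np.floor(f).astype(int), ncell - 1)
    cell = np.maximum(cell, 0)
    u = f - cell
    pk = _perm_index_of_local(perms, u)
    flat_cell = np.ravel_multi_index(tuple(cell.T), tuple(ncell))
    keep[flat_cell, pk] = True

    cells_k, perms_k = np.nonzero(keep)
    base = grid[cells_k]  # (m, dim)
    node_grid = tuple(ncell + 1)
    elem_nodes = np.empty((len(cells_k), dim + 1), dtype=np.int64)
    for v in range(dim + 1):
        coords = base + offs[perms_k, v]
        elem_nodes[:, v] = np.ravel_multi_index(tuple(coords.T), node_grid)

    used = np.unique(elem_nodes)
    remap = np.full(int(np.prod(node_grid)), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    elements = remap[elem_nodes]
    node_idx = np.stack(np.unravel_index(used, node_grid), axis=-1)
    nodes = lo + node_idx * step

    mesh = SimplicialMesh(nodes, elements)  # enforces orientation
    if snap:
        snapped = _snap_outside_nodes(
            domain, mesh.nodes, mesh.elements, float(step.max())
        )
        mesh = SimplicialMesh(snapped, mesh.elements)
    return mesh


def _touches_mask(domain: Domain, pts, tol=1e-9):
    """True where a world point touches at least one foreground cell
    (points exactly on cell boundaries count as touching all adjacent)."""
    f = domain.index_of_world(pts)
    lo_i = np.ceil(f - 0.5 - tol).astype(int)
    hi_i = np.floor(f + 0.5 + tol).astype(int)
    out = np.zeros(len(pts), dtype=bool)
    shape = np.array(domain.shape)
    span = hi_i - lo_i
    for off in itertools.product(*[range(int(s) + 1) for s in span.max(axis=0)]):
        ci = lo_i + np.minimum(np.array(off), span)
        ok = np.all((ci >= 0) & (ci < shape), axis=1)
        hit = np.zeros(len(pts), dtype=bool)
        hit[ok] = domain.mask[tuple(ci[ok].T)]
        out |= hit
    return out


def _snap_outside_nodes(domain, nodes, elements, cap):
    """Move nodes outside the mask onto the mask surface (nearest point of
    the nearest foreground cell), capped at one lattice edge and reverted
    where it would invert an incident element."""
    outside = ~_touches_mask(domain, nodes)
    if not outside.any():
        return nodes
    _, near = ndimage.distance_transform_edt(
        ~domain.mask, sampling=domain.spacing, return_indices=True
    )
    nodes = nodes.copy()
    moved = np.flatnonzero(outside)
    f = np.rint(domain.index_of_world(nodes[moved])).astype(int)
    f = np.clip(f, 0, np.array(domain.shape) - 1)
    tgt_idx = np.stack([near[(a,) + tuple(f.T)] for a in range(domain.dim)], axis=-1)
    center = domain.world_of_index(tgt_idx)
    half = 0.5 * np.asarray(domain.spacing)
    # nearest point of the cell's box: lies on the mask surface
    tgt = np.clip(nodes[moved], center - half, center + half)
    shift = np.linalg.norm(tgt - nodes[moved], axis=1)
    ok = shift <= cap * (1 + 1e-9)
    snapped = moved[ok]
    old = nodes[snapped].copy()
    nodes[snapped] = tgt[ok]
    # revert snaps that invert an incident element
    for _ in range(len(snapped)):
        pts = nodes[elements]
        det = np.linalg.det(pts[:, 1:, :] - pts[:, :1, :])
        bad = np.unique(elements[det <= 0])
        sel = np.isin(snapped, bad)
        if not sel.any():
            break
        nodes[snapped[sel]] = old[sel]
        keep = ~sel
        snapped, old = snapped[keep], old[keep]
    return nodes


def generate_mesh_2d(domain: Domain, target_edge: float, snap: bool = True) -> SimplicialMesh:
    """Conforming triangulation covering a 2D domain.

    ``target_edge`` is the lattice step in world units; median edge length
    comes out within a factor two of it (lattice edges are the step and its
    diagonal).
    """
    if domain.dim != 2:
        raise DomainError("generate_mesh_2d requires a 2D domain")
    return _generate_lattice_mesh(domain, float(target_edge), snap=snap)


def generate_mesh_3d(domain: Domain, target_edge: float, snap: bool = True) -> SimplicialMesh:
    """Conforming tetrahedral mesh covering a 3D domain (Kuhn lattice)."""
    if domain.dim != 3:
        raise DomainError("generate_mesh_3d requires a 3D domain")
    return _generate_lattice_mesh(domain, float(target_edge), snap=snap)


# ------------------------------------------------------------------- I/O --

def export_mesh(mesh: SimplicialMesh, path) -> None:
    """Write a mesh as Gmsh v2.2 ASCII (.msh), VTK legacy ASCII (.vtk) or
    OFF (.off; triangle meshes only)."""
    path = Path(path)
    ext = path.suffix.lower()
    nodes3 = np.zeros((mesh.n_nodes, 3))
    nodes3[:, : mesh.dim] = mesh.nodes
    if ext == ".msh":
        etype = 2 if mesh.dim == 2 else 4
        with open(path, "w") as fh:
            fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n")
            fh.write(f"{mesh.n_nodes}\n")
            for i, p in enumerate(nodes3, start=1):
                fh.write(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            fh.write("$EndNodes\n$Elements\n")
            fh.write(f"{mesh.n_elements}\n")
            for i, el in enumerate(mesh.elements, start=1):
                conn = " ".join(str(v + 1) for v in el)
                fh.write(f"{i} {etype} 2 0 0 {conn}\n")
            fh.write("$EndElements\n")
    elif ext == ".vtk":
        ctype = 5 if mesh.dim == 2 else 10
        d1 = mesh.dim + 1
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\ncdt mesh\nASCII\n")
            fh.write("DATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {mesh.n_nodes} double\n")
            for p in nodes3:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (d1 + 1)}\n")
            for el in mesh.elements:
                fh.write(f"{d1} " + " ".join(str(v) for v in el) + "\n")
            fh.write(f"CELL_TYPES {mesh.n_elements}\n")
            for _ in range(mesh.n_elements):
                fh.write(f"{ctype}\n")
    elif ext == ".off":
        if mesh.dim != 2:
            raise MeshError("OFF export supports triangle meshes only")
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{mesh.n_nodes} {mesh.n_elements} 0\n")
            for p in nodes3:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            for el in mesh.elements:
                fh.write("3 " + " ".join(str(v) for v in el) + "\n")
    else:
        raise MeshError(f"unsupported mesh format {ext!r}")


def _finish_import(pts3, cells, kinds):
    kinds = set(kinds)
    if len(kinds) != 1:
        raise MeshError("mixed-element meshes are rejected")
    nv = kinds.pop()
    if nv == 3:
        if np.any(np.abs(pts3[:, 2]) > 1e-12):
            raise MeshError("triangle mesh with non-planar z is not supported")
        return SimplicialMesh(pts3[:, :2], np.asarray(cells))
    if nv == 4:
        return SimplicialMesh(pts3, np.asarray(cells))
    raise MeshError(f"non-simplicial cell with {nv} vertices rejected")


def import_mesh(path) -> SimplicialMesh:
    """Read Gmsh v2.2 ASCII, VTK legacy ASCII or OFF.  Non-simplicial or
    mixed-element meshes are rejected."""
    path = Path(path)
    ext = path.suffix.lower()
    text = path.read_text().splitlines()
    if ext == ".msh":
        return _import_gmsh(text)
    if ext == ".vtk":
        return _import_vtk(text)
    if ext == ".off":
        return _import_off(text)
    raise MeshError(f"unsupported mesh format {ext!r}")


def _import_gmsh(lines):
    it = iter(lines)
    pts = {}
    cells, kinds = [], []
    for line in it:
        tag = line.strip()
        if tag == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                pts[int(parts[0])] = [float(x) for x in parts[1:4]]
        elif tag == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                conn = [int(x) for x in parts[3 + ntags:]]
                if etype in (1, 15):  # points/lines: boundary markers
                    continue
                if etype == 2:
                    kinds.append(3)
                elif etype == 4:
                    kinds.append(4)
                else:
                    raise MeshError(f"non-simplicial Gmsh element type {etype}")
                cells.append(conn)
    ids = sorted(pts)
    remap = {pid: i for i, pid in enumerate(ids)}
    pts3 = np.array([pts[pid] for pid in ids])
    cells = [[remap[v] for v in c] for c in cells]
    return _finish_import(pts3, cells, kinds)


def _import_vtk(lines):
    i = 0
    pts3 = None
    cells, types = [], []
    while i < len(lines):
        parts = lines[i].split()
        if parts[:1] == ["POINTS"]:
            n = int(parts[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            pts3 = np.array(vals).reshape(n, 3)
            continue
        if parts[:1] == ["CELLS"]:
            m = int(parts[1])
            i += 1
            for _ in range(m):
                row = [int(x) for x in lines[i].split()]
                cells.append(row[1:])
                i += 1
            continue
        if parts[:1] == ["CELL_TYPES"]:
            m = int(parts[1])
            i += 1
            vals = []
            while len(vals) < m:
                vals.extend(int(x) for x in lines[i].split())
                i += 1
            types = vals
            continue
        i += 1
    if pts3 is None or not cells:
        raise MeshError("malformed VTK file")
    kinds = []
    for t, c in zip(types, cells):
        if t == 5:
            kinds.append(3)
        elif t == 10:
            kinds.append(4)
        else:
            raise MeshError(f"non-simplicial VTK cell type {t}")
    return _finish_import(pts3, cells, kinds)


def _import_off(lines):
    lines = [l for l in lines if l.strip() and not l.strip().startswith("#")]
    if lines[0].strip() != "OFF":
        raise MeshError("not an OFF file")
    nv, nf, _ = (int(x) for x in lines[1].split())
    pts3 = np.array([[float(x) for x in lines[2 + i].split()[:3]] for i in range(nv)])
    cells, kinds = [], []
    for i in range(nf):
        row = [int(x) for x in lines[2 + nv + i].split()]
        kinds.append(row[0])
        cells.append(row[1 : 1 + row[0]])
    return _finish_import(pts3, cells, kinds)


def coverage_fraction(mesh: SimplicialMesh, domain: Domain) -> float:
    """Fraction of foreground cell centers covered by the mesh footprint."""
    centers = domain.world_of_index(np.argwhere(domain.mask))
    hit = 0
    for c in centers:
        if mesh.locate_point(c) is not None:
            hit += 1
    return hit / len(centers)
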