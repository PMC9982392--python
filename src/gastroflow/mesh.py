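"""Voxel finite-volume discretization of the lumen geometry.

The lumen is sampled on a uniform Cartesian grid (cubic cells).  A cell is
fluid when its centre lies inside the implicit lumen; the largest connected
fluid component is kept.  Faces are axis-aligned with area h^2: interior
faces carry an owner/neighbour pair, boundary faces carry a patch tag
(INLET, OUTLET, WALL).  Wall faces additionally store the distance from the
owning cell centre to the true lumen wall along the face normal, estimated
from the signed-distance field — this sub-cell correction is what lets a
modest uniform grid meet the pipe-flow oracle without local refinement.

All mesh quantities are stored in SI metres; the mm -> m conversion happens
exactly once, in :func:`discretize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph

from gastroflow.anatomy import MM, GeometryError, LumenGeometry

__all__ = ["VolumeMesh", "discretize", "Tag", "write_vtk"]


class Tag:
    WALL = 0
    INLET = 1
    OUTLET = 2
    SYMMETRY = 3  # free-slip mid-plane faces of a planar (2D) mesh


@dataclass
class VolumeMesh:
    """Uniform voxel mesh with labelled boundary patches and diagnostic cuts."""

    origin: np.ndarray  # (3,) m, lower corner of the grid
    h: float  # cell size, m
    shape: tuple[int, int, int]
    cell_index: np.ndarray  # (nx,ny,nz) int32, -1 outside the fluid
    ijk: np.ndarray  # (N,3) grid coordinates of each fluid cell
    cell_centers: np.ndarray  # (N,3) m
    # interior faces: neighbour = owner shifted +1 along `axis`
    face_owner: np.ndarray
    face_neigh: np.ndarray
    face_axis: np.ndarray
    # boundary faces
    bnd_cell: np.ndarray
    bnd_axis: np.ndarray
    bnd_side: np.ndarray  # +1 / -1: outward normal sign along the axis
    bnd_tag: np.ndarray
    bnd_wall_dist: np.ndarray  # m, centre-to-wall distance along the face normal
    sections: dict = field(default_factory=dict)  # name -> (face ids, sign)
    geometry: LumenGeometry | None = None

    # -- basic quantities --------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cell_centers)

    @property
    def n_faces(self) -> int:
        return len(self.face_owner)

    @property
    def face_area(self) -> float:
        return self.h**2

    @property
    def cell_volume(self) -> float:
        return self.h**3

    def total_volume(self) -> float:
        return self.n_cells * self.cell_volume

    def boundary_center(self, i: int) -> np.ndarray:
        c = self.cell_centers[self.bnd_cell[i]].copy()
        c[self.bnd_axis[i]] += 0.5 * self.h * self.bnd_side[i]
        return c

    def boundary_centers(self) -> np.ndarray:
        c = self.cell_centers[self.bnd_cell].copy()
        c[np.arange(len(c)), self.bnd_axis] += 0.5 * self.h * self.bnd_side
        return c

    # -- connectivity ------------------------------------------------------

    def adjacency(self, blocked_faces: np.ndarray | None = None) -> sparse.csr_matrix:
        """Cell adjacency graph, optionally with a set of interior faces removed."""
        keep = np.ones(self.n_faces, dtype=bool)
        if blocked_faces is not None:
            keep[np.asarray(blocked_faces)] = False
        o, n = self.face_owner[keep], self.face_neigh[keep]
        data = np.ones(len(o))
        adj = sparse.coo_matrix(
            (np.r_[data, data], (np.r_[o, n], np.r_[n, o])),
            shape=(self.n_cells, self.n_cells),
        )
        return adj.tocsr()

    def connected(self, cell_a: int, cell_b: int, blocked_faces=None) -> bool:
        _, labels = csgraph.connected_components(self.adjacency(blocked_faces), directed=False)
        return bool(labels[cell_a] == labels[cell_b])

    def patch_cells(self, tag: int) -> np.ndarray:
        return np.unique(self.bnd_cell[self.bnd_tag == tag])

    def mirror_z_permutation(self) -> np.ndarray | None:
        """Cell permutation for the z-mirror plane of the grid, if the fluid
        mask is symmetric under it; None otherwise."""
        nz = self.shape[2]
        i, j, k = self.ijk.T
        mirrored = self.cell_index[i, j, nz - 1 - k]
        if np.any(mirrored < 0):
            return None
        return mirrored

    def cell_at(self, point_m: np.ndarray) -> int:
        """Index of the fluid cell containing a point (m); -1 if outside."""
        ijk = np.floor((np.asarray(point_m) - self.origin) / self.h).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.array(self.shape)):
            return -1
        return int(self.cell_index[tuple(ijk)])


def _pick_face_plane(origin: float, h: float, n: int, value: float) -> int:
    """Interior face-plane index (1..n-1) nearest to a coordinate value."""
    k = int(round((value - origin) / h))
    return int(np.clip(k, 1, n - 1))


def discretize(
    geom: LumenGeometry, target_cell_size: float, planar: bool = False
) -> VolumeMesh:
    """Voxelize the lumen at the given cell size (mm).

    With ``planar=True`` the mesh is a single layer of cells on the coronal
    mid-plane (z = 0) whose anterior/posterior faces are free-slip symmetry
    faces — the 2D mid-plane model of the tract.  Refuses cell sizes that
    cannot resolve the narrowest channel of the geometry (pylorus,
    anastomotic slot or partition channel).
    """
    if target_cell_size <= 0:
        raise GeometryError("target_cell_size must be positive")
    if target_cell_size > geom.min_channel_diameter / 2.0:
        raise GeometryError(
            f"cell size {target_cell_size} mm cannot resolve the narrowest channel "
            f"of the geometry ({geom.min_channel_diameter:.1f} mm across: pylorus, "
            "anastomotic slot or partition channel); refine the mesh"
        )
    h = float(target_cell_size)
    # align the grid so the open port planes coincide with face planes; a
    # second port on the same axis is snapped to the nearest face plane
    constraints: dict[int, dict[int, float]] = {}
    for axis, side, value in (geom.inlet_port, geom.outlet_port):
        constraints.setdefault(axis, {})[side] = value
    origin = np.zeros(3)
    ncells = np.zeros(3, dtype=int)
    for a in range(3):
        lo, hi = geom.bbox[a]
        c = constraints.get(a, {})
        if +1 in c:
            n = int(np.ceil((c[+1] - min(lo, c.get(-1, lo))) / h)) + (0 if -1 in c else 1)
            origin[a], ncells[a] = c[+1] - n * h, n
        elif -1 in c:
            n = int(np.ceil((hi - c[-1]) / h)) + 1
            origin[a], ncells[a] = c[-1], n
        else:
            # centred so a mirror-symmetric bounding box yields a
            # mirror-symmetric grid (centers map onto centers)
            n = int(np.ceil((hi - lo) / h))
            origin[a], ncells[a] = 0.5 * (lo + hi) - 0.5 * n * h, n

    def snapped_port(port):
        a, side, value = port
        k = int(round((value - origin[a]) / h))
        return a, side, origin[a] + k * h

    inlet_port = snapped_port(geom.inlet_port)
    outlet_port = snapped_port(geom.outlet_port)
    if planar:
        origin[2], ncells[2] = -0.5 * h, 1
    ox, oy, oz = origin
    nx, ny, nz = (int(v) for v in ncells)

    xs = ox + (np.arange(nx) + 0.5) * h
    ys = oy + (np.arange(ny) + 0.5) * h
    zs = oz + (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    d = geom.sdf(pts).reshape(nx, ny, nz)
    fluid = d < 0.0
    # clip any lumen extending past the (snapped) port planes
    coords = (X, Y, Z)
    for a, side, value in (inlet_port, outlet_port):
        fluid &= side * (coords[a] - value) < 0.0

    labels, n_lab = ndimage.label(fluid)
    if n_lab == 0:
        raise GeometryError("no fluid cells at this resolution")
    if n_lab > 1:
        sizes = ndimage.sum_labels(fluid, labels, index=np.arange(1, n_lab + 1))
        fluid = labels == (1 + int(np.argmax(sizes)))

    cell_index = -np.ones((nx, ny, nz), dtype=np.int32)
    ijk = np.argwhere(fluid)
    cell_index[fluid] = np.arange(len(ijk), dtype=np.int32)
    centers_mm = np.column_stack([xs[ijk[:, 0]], ys[ijk[:, 1]], zs[ijk[:, 2]]])

    # interior faces per axis
    owners, neighs, axes = [], [], []
    for a in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(0, -1)
        sl_hi[a] = slice(1, None)
        both = fluid[tuple(sl_lo)] & fluid[tuple(sl_hi)]
        o = cell_index[tuple(sl_lo)][both]
        n_ = cell_index[tuple(sl_hi)][both]
        owners.append(o)
        neighs.append(n_)
        axes.append(np.full(len(o), a, dtype=np.int8))
    face_owner = np.concatenate(owners)
    face_neigh = np.concatenate(neighs)
    face_axis = np.concatenate(axes)

    # boundary faces
    b_cell, b_axis, b_side = [], [], []
    for a in range(3):
        for side in (-1, +1):
            shifted = np.roll(fluid, -side, axis=a)
            # cells at the grid edge have no neighbour on that side
            edge = np.zeros_like(fluid)
            idx = [slice(None)] * 3
            idx[a] = -1 if side == 1 else 0
            edge[tuple(idx)] = True
            exposed = fluid & (~shifted | edge)
            cells = cell_index[exposed]
            b_cell.append(cells)
            b_axis.append(np.full(len(cells), a, dtype=np.int8))
            b_side.append(np.full(len(cells), side, dtype=np.int8))
    bnd_cell = np.concatenate(b_cell)
    bnd_axis = np.concatenate(b_axis)
    bnd_side = np.concatenate(b_side)

    # tag boundary faces lying on the open port planes
    face_coord = centers_mm[bnd_cell, bnd_axis] + 0.5 * h * bnd_side
    tol = 0.51 * h
    bnd_tag = np.full(len(bnd_cell), Tag.WALL, dtype=np.int8)
    if planar:
        bnd_tag[bnd_axis == 2] = Tag.SYMMETRY
    for tag, (axis, side, value) in (
        (Tag.INLET, inlet_port),
        (Tag.OUTLET, outlet_port),
    ):
        on_port = (bnd_axis == axis) & (bnd_side == side) & (np.abs(face_coord - value) < tol)
        bnd_tag[on_port] = tag

    # wall distances along the face normal from the signed-distance field
    wall = bnd_tag == Tag.WALL
    pw = centers_mm[bnd_cell[wall]]
    dw = -geom.sdf(pw)  # distance of the cell centre to the nearest wall (mm)
    eps = 0.2 * h
    grad = np.zeros((len(pw), 3))
    for a in range(3):
        step = np.zeros(3)
        step[a] = eps
        grad[:, a] = (geom.sdf(pw + step) - geom.sdf(pw - step)) / (2 * eps)
    gnorm = np.linalg.norm(grad, axis=1)
    gnorm = np.where(gnorm < 1e-6, 1.0, gnorm)
    comp = np.abs(grad[np.arange(len(pw)), bnd_axis[wall]]) / gnorm
    d_normal = (dw / gnorm) / np.clip(comp, 0.35, 1.0)
    d_normal = np.clip(d_normal, 0.1 * h, 1.2 * h)
    bnd_wall_dist = np.full(len(bnd_cell), 0.5 * h)
    bnd_wall_dist[wall] = d_normal

    mesh = VolumeMesh(
        origin=np.array([ox, oy, oz]) * MM,
        h=h * MM,
        shape=(nx, ny, nz),
        cell_index=cell_index,
        ijk=ijk,
        cell_centers=centers_mm * MM,
        face_owner=face_owner,
        face_neigh=face_neigh,
        face_axis=face_axis,
        bnd_cell=bnd_cell,
        bnd_axis=bnd_axis,
        bnd_side=bnd_side,
        bnd_tag=bnd_tag,
        bnd_wall_dist=bnd_wall_dist * MM,
        geometry=geom,
    )

    # diagnostic cross-sections
    grid_orig = (ox, oy, oz)
    grid_n = (nx, ny, nz)
    face_mid = centers_mm[face_owner] + 0.0
    face_mid[np.arange(len(face_owner)), face_axis] += 0.5 * h
    for name, spec in geom.sections.items():
        a = spec.axis
        k = _pick_face_plane(grid_orig[a], h, grid_n[a], spec.value)
        plane_coord = grid_orig[a] + k * h
        on_plane = (face_axis == a) & (np.abs(face_mid[:, a] - plane_coord) < 0.01 * h)
        plane_ids = np.nonzero(on_plane)[0]
        if len(plane_ids) == 0:
            raise GeometryError(f"cross-section {name} captured no faces")
        inside = spec.selector(face_mid[plane_ids], 1.05 * h)
        ids = plane_ids[inside]
        if len(ids) == 0:
            raise GeometryError(f"cross-section {name} captured no faces")
        # completeness: no selected face may touch an unselected fluid face of
        # the same plane (the cut must be bounded by walls, not the selector)
        tr = [ax_ for ax_ in range(3) if ax_ != a]
        key_all = {tuple(row) for row in ijk[face_owner[plane_ids]][:, tr]}
        key_sel = {tuple(row) for row in ijk[face_owner[ids]][:, tr]}
        for ki, kj in key_sel:
            for dk in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb_key = (ki + dk[0], kj + dk[1])
                if nb_key in key_all and nb_key not in key_sel:
                    raise GeometryError(
                        f"cross-section {name} is an incomplete cut of the local "
                        "conduit (open fluid beyond the selected faces)"
                    )
        mesh.sections[name] = (ids, spec.positive)
    return mesh


# ---------------------------------------------------------------------------
# legacy-VTK export (visualization convenience)
# ---------------------------------------------------------------------------


def write_vtk(mesh: VolumeMesh, path: str | Path, cell_data: dict | None = None) -> Path:
    """Write the voxel mesh (and optional per-cell fields) as legacy ASCII VTK."""
    path = Path(path)
    h = mesh.h
    ijk = mesh.ijk
    # unique vertex grid
    corners = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]])
    verts = {}
    cells = np.empty((mesh.n_cells, 8), dtype=np.int64)
    for ci in range(mesh.n_cells):
        for vi, c in enumerate(corners):
            key = tuple(ijk[ci] + c)
            if key not in verts:
                verts[key] = len(verts)
            cells[ci, vi] = verts[key]
    pts = np.array(list(verts.keys()), dtype=float) * h + mesh.origin
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ngastroflow voxel mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} float\n")
        np.savetxt(f, pts, fmt="%.6e")
        f.write(f"CELLS {mesh.n_cells} {mesh.n_cells * 9}\n")
        np.savetxt(f, np.column_stack([np.full(mesh.n_cells, 8), cells]), fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_cells}\n")
        np.savetxt(f, np.full(mesh.n_cells, 12), fmt="%d")  # VTK_HEXAHEDRON
        if cell_data:
            f.write(f"CELL_DATA {mesh.n_cells}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.6e")
                else:
                    f.write(f"VECTORS {name} float\n")
                    np.savetxt(f, arr, fmt="%.6e")
    return path
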