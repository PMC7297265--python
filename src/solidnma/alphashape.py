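"""Alpha-shape tetrahedral solids.

The solid model of a structure is the subcomplex of the Delaunay
tetrahedralization of its nodes that keeps exactly the tetrahedra whose
circumsphere radius is ≤ alpha (3-simplices only).  The nodes of the solid
are the input coordinates themselves — no new vertices are ever introduced,
which is what lets normal modes live directly on the atoms.

alpha plays the role the cutoff distance plays in elastic network models:
small alpha carves a tight, possibly disconnected shape; alpha → ∞ recovers
the full Delaunay tetrahedralization (convex hull).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import Delaunay, QhullError

from .errors import (
    BracketingError,
    DegenerateGeometryError,
    EmptyShapeError,
    FormatError,
    TooFewNodesError,
)
from .pointset import PointSet

#: tets thinner than this (Å³) are treated as slivers and dropped before
#: filtering; exact lattices produce zero-volume cells that would break FEM.
SLIVER_VOLUME = 1e-9


# ---------------------------------------------------------------------------
# geometry primitives


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Unsigned volumes (Å³) of tetrahedra ``tets`` over ``nodes``."""
    p = nodes[tets]
    e = p[:, 1:] - p[:, :1]
    return np.abs(np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2]))) / 6.0


def circumradii(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumsphere radii of tetrahedra; inf for (near-)degenerate cells.

    The circumcenter c satisfies |c − pᵢ| = |c − p₀| for i = 1..3, a 3×3
    linear system 2(pᵢ − p₀)·c = |pᵢ|² − |p₀|².
    """
    p = nodes[tets]
    a = 2.0 * (p[:, 1:] - p[:, :1])  # (T, 3, 3)
    b = np.einsum("ijk,ijk->ij", p[:, 1:], p[:, 1:]) - np.einsum(
        "ik,ik->i", p[:, 0], p[:, 0]
    )[:, None]
    det = np.linalg.det(a)
    ok = np.abs(det) > 1e-300
    r = np.full(len(tets), np.inf)
    if ok.any():
        c = np.linalg.solve(a[ok], b[ok][..., None])[..., 0]
        r[ok] = np.linalg.norm(c - p[ok, 0], axis=1)
    return r


def circumradius(p0, p1, p2, p3) -> float:
    """Circumsphere radius of a single tetrahedron (Å)."""
    pts = np.asarray([p0, p1, p2, p3], dtype=float)
    vol = tet_volumes(pts, np.array([[0, 1, 2, 3]]))[0]
    if vol < SLIVER_VOLUME:
        raise DegenerateGeometryError("coplanar or degenerate tetrahedron")
    return float(circumradii(pts, np.array([[0, 1, 2, 3]]))[0])


# ---------------------------------------------------------------------------
# meshes


@dataclass
class TetMesh:
    """An alpha-shape solid: node coordinates plus kept tetrahedra.

    ``nodes`` are exactly the input point coordinates (some may be unused by
    ``tets``); ``volumes`` and ``radii`` are per-tet volume and circumradius.
    """

    nodes: np.ndarray
    tets: np.ndarray
    volumes: np.ndarray = None
    radii: np.ndarray = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=int).reshape(-1, 4)
        if self.volumes is None:
            self.volumes = tet_volumes(self.nodes, self.tets)
        if self.radii is None:
            self.radii = circumradii(self.nodes, self.tets)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def used_nodes(self) -> np.ndarray:
        """Indices of nodes that are a vertex of at least one tetrahedron."""
        return np.unique(self.tets)

    @property
    def volume(self) -> float:
        return float(self.volumes.sum())


@dataclass
class TriMesh:
    """A triangle surface over (a subset of) the solid's nodes."""

    nodes: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)

    @property
    def used_nodes(self) -> np.ndarray:
        return np.unique(self.triangles)

    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    @property
    def area(self) -> float:
        return float(self.areas().sum())


def _coords(points) -> np.ndarray:
    if isinstance(points, PointSet):
        return points.coords
    return np.asarray(points, dtype=float)


def _delaunay(coords: np.ndarray):
    if len(coords) < 4:
        raise TooFewNodesError("need at least 4 points for a tetrahedralization")
    try:
        tri = Delaunay(coords)
    except QhullError as exc:  # all coplanar, duplicates only, …
        raise DegenerateGeometryError(f"Delaunay failed: {exc}") from exc
    vols = tet_volumes(coords, tri.simplices)
    keep = vols >= SLIVER_VOLUME
    tets = tri.simplices[keep]
    if len(tets) == 0:
        raise DegenerateGeometryError("all Delaunay cells are degenerate slivers")
    return tets, vols[keep]


def build_alpha_shape(points, alpha: float | None = None) -> TetMesh:
    """Alpha-shape solid of ``points`` (PointSet or (N, 3) array).

    Keeps the Delaunay tetrahedra whose circumradius is ≤ ``alpha``.
    ``alpha=None`` uses :func:`critical_alpha`, the smallest value whose
    shape still touches every input point.  ``alpha=inf`` keeps the full
    Delaunay tetrahedralization.
    """
    coords = _coords(points)
    tets, vols = _delaunay(coords)
    radii = circumradii(coords, tets)
    if alpha is None:
        alpha = _critical_alpha_from(tets, radii, len(coords))
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    keep = radii <= alpha * (1.0 + 1e-12)
    if not keep.any():
        raise EmptyShapeError(
            f"alpha={alpha} Å filters out all {len(tets)} tetrahedra "
            f"(smallest circumradius {radii.min():.3f} Å)"
        )
    return TetMesh(coords, tets[keep], vols[keep], radii[keep])


def _critical_alpha_from(tets: np.ndarray, radii: np.ndarray, n: int) -> float:
    # a point is enclosed once alpha reaches the smallest circumradius among
    # its incident tets; all points are enclosed at the max of those minima.
    min_r = np.full(n, np.inf)
    for col in range(4):
        np.minimum.at(min_r, tets[:, col], radii)
    if not np.all(np.isfinite(min_r)):
        raise DegenerateGeometryError(
            "some points belong to no finite-circumradius tetrahedron"
        )
    return float(min_r.max())


def critical_alpha(points) -> float:
    """Smallest alpha whose shape has every input point as a tet vertex."""
    coords = _coords(points)
    tets, _ = _delaunay(coords)
    return _critical_alpha_from(tets, circumradii(coords, tets), len(coords))


def shape_volume(mesh: TetMesh) -> float:
    """Total volume (Å³) of the solid."""
    return mesh.volume


def boundary_surface(mesh: TetMesh) -> TriMesh:
    """Boundary triangles (faces belonging to exactly one kept tet), outward.

    Orientation: each boundary face is wound so its normal points away from
    the opposite vertex of its owning tetrahedron.  Candidate faces exposed
    only because a zero-volume sliver was dropped (solid on both sides) are
    rejected by probing just outside each face against the incident tets.
    """
    faces = mesh.tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]].reshape(-1, 3)
    opp = mesh.tets.reshape(-1)  # opposite vertex of face k is tets.flat[k]
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inv] == 1
    tri = faces[on_boundary]
    opp = opp[on_boundary]
    # flip windings whose normal points toward the opposite vertex
    p = mesh.nodes[tri]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    inward = np.einsum("ij,ij->i", n, mesh.nodes[opp] - p[:, 0]) > 0
    tri[inward] = tri[inward][:, [0, 2, 1]]
    keep = _probe_outside(mesh, tri)
    return TriMesh(mesh.nodes, tri[keep])


def _probe_outside(mesh: TetMesh, tri: np.ndarray) -> np.ndarray:
    """True for faces whose outward side is actually outside the solid."""
    if len(tri) == 0:
        return np.zeros(0, dtype=bool)
    p = mesh.nodes[tri]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    n = n / np.where(nn > 0, nn, 1.0)
    edge = np.sqrt(np.squeeze(nn, -1))  # characteristic face length scale
    probe = p.mean(axis=1) + (1e-6 * edge)[:, None] * n

    # incident tets per face vertex via a vertex -> tets CSR incidence
    t_idx = np.repeat(np.arange(mesh.n_tets), 4)
    v_idx = mesh.tets.reshape(-1)
    order = np.argsort(v_idx, kind="stable")
    v_sorted, t_sorted = v_idx[order], t_idx[order]
    starts = np.searchsorted(v_sorted, np.arange(mesh.n_nodes + 1))

    pm = mesh.nodes[mesh.tets]
    jinv = np.linalg.inv(np.transpose(pm[:, 1:] - pm[:, :1], (0, 2, 1)))
    keep = np.ones(len(tri), dtype=bool)
    for f in range(len(tri)):
        cand = np.unique(np.concatenate([
            t_sorted[starts[v]:starts[v + 1]] for v in tri[f]
        ]))
        bary = np.einsum(
            "tij,tj->ti", jinv[cand], probe[f] - pm[cand, 0]
        )
        inside = (
            (bary >= -1e-9).all(axis=1) & (bary.sum(axis=1) <= 1.0 + 1e-9)
        )
        if inside.any():
            keep[f] = False  # solid on both sides: an internal fin
    return keep


def alpha_for_volume(
    points, target_volume: float, bracket: tuple[float, float] | None = None,
    rtol: float = 1e-3,
) -> float:
    """The smallest alpha whose shape volume matches ``target_volume``.

    Volume versus alpha is a non-decreasing step function with one step per
    distinct circumradius, so the search is exact over that finite candidate
    set.  Returns the smallest alpha of the plateau closest to the target;
    warns if the closest plateau misses the target by more than ``rtol``.
    """
    coords = _coords(points)
    tets, vols = _delaunay(coords)
    radii = circumradii(coords, tets)
    finite = np.isfinite(radii)
    order = np.argsort(radii[finite])
    r_sorted = radii[finite][order]
    v_cum = np.cumsum(vols[finite][order])
    # collapse ties: plateau value after the last tet of each distinct radius
    r_steps, last = np.unique(r_sorted, return_index=True)
    last = np.r_[last[1:] - 1, len(r_sorted) - 1]
    v_steps = v_cum[last]
    if bracket is not None:
        lo, hi = bracket
        sel = (r_steps >= lo) & (r_steps <= hi)
        if not sel.any():
            raise BracketingError("no alpha step inside the bracket")
        r_steps, v_steps = r_steps[sel], v_steps[sel]
    if target_volume > v_steps[-1] * (1 + rtol) or target_volume <= 0:
        raise BracketingError(
            f"target volume {target_volume:.4g} outside attainable range "
            f"(0, {v_steps[-1]:.4g}]"
        )
    i = int(np.argmin(np.abs(v_steps - target_volume)))
    err = abs(v_steps[i] - target_volume) / target_volume
    if err > rtol:
        warnings.warn(
            f"closest attainable volume misses target by {err:.2%}",
            stacklevel=2,
        )
    return float(r_steps[i])


def connected_components(mesh: TetMesh, by: str = "vertex") -> list[TetMesh]:
    """Split a solid into connected components, largest (by node count) first.

    ``by='vertex'`` (default) connects tets sharing any vertex; ``by='face'``
    requires a shared triangular face.  Component meshes keep the full node
    array (indices stay valid) and partition the tetrahedra.
    """
    if by == "vertex":
        i = np.repeat(np.arange(mesh.n_tets), 4)
        j = mesh.tets.reshape(-1)
        # tets sharing a node are connected through that node: build a
        # bipartite tet–node graph and take components
        n = mesh.n_tets + mesh.n_nodes
        g = coo_matrix(
            (np.ones(len(i)), (i, mesh.n_tets + j)), shape=(n, n)
        )
        _, lab = _cc(g + g.T, directed=False)
        tet_lab = lab[: mesh.n_tets]
    elif by == "face":
        faces = mesh.tets[:, [[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv = np.unique(key, axis=0, return_inverse=True)
        owner = np.repeat(np.arange(mesh.n_tets), 4)
        order = np.argsort(inv, kind="stable")
        inv_s, own_s = inv[order], owner[order]
        same = inv_s[1:] == inv_s[:-1]
        i, j = own_s[:-1][same], own_s[1:][same]
        g = coo_matrix(
            (np.ones(len(i)), (i, j)), shape=(mesh.n_tets, mesh.n_tets)
        )
        _, tet_lab = _cc(g + g.T, directed=False)
    else:
        raise ValueError("by must be 'vertex' or 'face'")
    comps = []
    for c in np.unique(tet_lab):
        sel = tet_lab == c
        comps.append(
            TetMesh(mesh.nodes, mesh.tets[sel], mesh.volumes[sel], mesh.radii[sel])
        )
    comps.sort(key=lambda m: len(m.used_nodes), reverse=True)
    return comps


# ---------------------------------------------------------------------------
# mesh export / import (4-node tetrahedral elements)


def export_mesh(mesh: TetMesh, path, fmt: str) -> None:
    """Write the solid as VTK legacy, Abaqus INP (C3D4) or GMSH MSH v2.2.

    Node numbering is 1-based in INP and MSH, 0-based in VTK, matching each
    format's convention.  Unused nodes are written too so indices round-trip.
    """
    fmt = fmt.lower()
    writers = {"vtk": _write_vtk, "inp": _write_inp, "msh": _write_msh}
    if fmt not in writers:
        raise ValueError(f"unknown mesh format {fmt!r}; use vtk, inp or msh")
    writers[fmt](mesh, path)


def _write_vtk(mesh: TetMesh, path) -> None:
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nalpha-shape solid\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y, z in mesh.nodes:
            f.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        f.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        for t in mesh.tets:
            f.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        f.write(f"CELL_TYPES {mesh.n_tets}\n")
        f.write("\n".join(["10"] * mesh.n_tets) + "\n")


def _write_inp(mesh: TetMesh, path) -> None:
    with open(path, "w") as f:
        f.write("*HEADING\nalpha-shape solid\n*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            f.write(f"{i}, {x:.6f}, {y:.6f}, {z:.6f}\n")
        f.write("*ELEMENT, TYPE=C3D4\n")
        for e, t in enumerate(mesh.tets, start=1):
            f.write(f"{e}, {t[0] + 1}, {t[1] + 1}, {t[2] + 1}, {t[3] + 1}\n")


def _write_msh(mesh: TetMesh, path) -> None:
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {x:.6f} {y:.6f} {z:.6f}\n")
        f.write(f"$EndNodes\n$Elements\n{mesh.n_tets}\n")
        for e, t in enumerate(mesh.tets, start=1):
            f.write(f"{e} 4 2 0 1 {t[0] + 1} {t[1] + 1} {t[2] + 1} {t[3] + 1}\n")
        f.write("$EndElements\n")


def import_mesh(path, fmt: str) -> TetMesh:
    """Minimal reader for the three exported formats (round-trip checks)."""
    fmt = fmt.lower()
    with open(path) as f:
        lines = f.read().splitlines()
    try:
        if fmt == "vtk":
            return _read_vtk(lines)
        if fmt == "inp":
            return _read_inp(lines)
        if fmt == "msh":
            return _read_msh(lines)
    except (ValueError, IndexError) as exc:
        raise FormatError(f"cannot parse {fmt} mesh: {exc}") from exc
    raise ValueError(f"unknown mesh format {fmt!r}")


def _read_vtk(lines) -> TetMesh:
    it = iter(lines)
    nodes, tets = None, []
    for line in it:
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            nodes = np.array(
                [next(it).split() for _ in range(n)], dtype=float
            )
        elif line.startswith("CELLS"):
            t = int(line.split()[1])
            for _ in range(t):
                parts = next(it).split()
                if parts[0] == "4":
                    tets.append([int(v) for v in parts[1:5]])
    return TetMesh(nodes, np.array(tets))


def _read_inp(lines) -> TetMesh:
    nodes, tets, section = [], [], None
    for line in lines:
        u = line.strip().upper()
        if u.startswith("*NODE"):
            section = "node"
        elif u.startswith("*ELEMENT"):
            section = "elem"
        elif u.startswith("*"):
            section = None
        elif section == "node" and line.strip():
            nodes.append([float(v) for v in line.split(",")[1:4]])
        elif section == "elem" and line.strip():
            tets.append([int(v) - 1 for v in line.split(",")[1:5]])
    return TetMesh(np.array(nodes), np.array(tets))


def _read_msh(lines) -> TetMesh:
    nodes, tets = [], []
    i = 0
    while i < len(lines):
        if lines[i] == "$Nodes":
            n = int(lines[i + 1])
            for k in range(n):
                nodes.append([float(v) for v in lines[i + 2 + k].split()[1:4]])
            i += n + 2
        elif lines[i] == "$Elements":
            t = int(lines[i + 1])
            for k in range(t):
                parts = lines[i + 2 + k].split()
                ntags = int(parts[2])
                if parts[1] == "4":
                    tets.append([int(v) - 1 for v in parts[3 + ntags:7 + ntags]])
            i += t + 2
        else:
            i += 1
    return TetMesh(np.array(nodes), np.array(tets))
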