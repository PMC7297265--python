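"""Shape-preserving non-uniform coarse-graining.

A structure's solid model is peeled layer by layer: the boundary nodes of
the current alpha shape form a surface layer whose triangle mesh is
simplified by quadric edge collapse down to a target fraction; the layer is
then removed and the interior is peeled again, until the interior is too
small to mesh, at which point any leftover interior points are thinned to
the same fraction by seeded voxel-grid downsampling.

The decimator collapses edges onto one of their endpoints (never a new
position), so the coarse-grained nodes are always an exact subset of the
input coordinates — the property that lets modes live on real atoms.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .alphashape import TriMesh, boundary_surface, build_alpha_shape
from .errors import DegenerateGeometryError
from .pointset import PointSet

__all__ = ["CoarsenSpec", "reduce_surface", "coarsen_structure"]


@dataclass
class CoarsenSpec:
    """Target retained fraction per layer, alpha (Å), peel depth, seed."""

    fraction: float = 0.25
    alpha: float | None = None
    n_layers: int = 1_000_000  # effectively "peel until exhausted"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")


# ---------------------------------------------------------------------------
# quadric edge-collapse decimation (endpoint-collapse variant)


def _face_quadrics(nodes: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex 4×4 error quadrics: sum of squared plane distances."""
    p = nodes[faces]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area = np.linalg.norm(n, axis=1)
    good = area > 1e-300
    n = np.where(good[:, None], n / np.where(good, area, 1.0)[:, None], 0.0)
    d = -np.einsum("ij,ij->i", n, p[:, 0])
    plane = np.concatenate([n, d[:, None]], axis=1)  # (F, 4)
    kp = np.einsum("fi,fj->fij", plane, plane)  # (F, 4, 4)
    q = np.zeros((len(nodes), 4, 4))
    for c in range(3):
        np.add.at(q, faces[:, c], kp)
    return q


def _vertex_error(q: np.ndarray, v: np.ndarray) -> float:
    h = np.array([v[0], v[1], v[2], 1.0])
    return float(h @ q @ h)


def decimate(mesh: TriMesh, fraction: float) -> TriMesh:
    """Quadric edge-collapse decimation to ≈ ``fraction`` of the faces.

    Edges collapse onto the endpoint with the smaller combined quadric
    error, so surviving vertices keep their original coordinates.  Collapses
    that would pinch the surface (edge with more than two common neighbour
    vertices) are skipped.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    faces = {tuple(f) for f in mesh.triangles.tolist()}
    if fraction == 1.0 or len(faces) <= 4:
        return TriMesh(mesh.nodes, np.array(sorted(faces)))
    target = max(4, int(round(fraction * len(faces))))
    nodes = mesh.nodes
    quad = _face_quadrics(nodes, mesh.triangles)

    vert_faces: dict[int, set] = {}
    for f in faces:
        for v in f:
            vert_faces.setdefault(v, set()).add(f)

    def neighbours(v):
        return {u for f in vert_faces.get(v, ()) for u in f if u != v}

    def edge_cost(a, b):
        qab = quad[a] + quad[b]
        ea, eb = _vertex_error(qab, nodes[a]), _vertex_error(qab, nodes[b])
        return (ea, a, b) if ea <= eb else (eb, b, a)  # (cost, keep, drop)

    heap = []
    version: dict[int, int] = {}
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[0], f[2])):
            if a > b:
                a, b = b, a
            cost, keep, drop = edge_cost(a, b)
            heapq.heappush(heap, (cost, a, b, keep, drop, 0, 0))

    def ver(v):
        return version.get(v, 0)

    n_faces = len(faces)
    while heap and n_faces > target:
        cost, a, b, keep, drop, va, vb = heapq.heappop(heap)
        if ver(a) != va or ver(b) != vb:
            continue  # stale entry
        if drop not in vert_faces or keep not in vert_faces:
            continue
        shared = neighbours(keep) & neighbours(drop)
        if len(shared) != 2:
            continue  # non-manifold or boundary pinch; skip
        # collapse drop -> keep
        removed = [f for f in vert_faces[drop] if keep in f]
        changed = [f for f in vert_faces[drop] if keep not in f]
        if n_faces - len(removed) < 4:
            break
        for f in removed:
            for v in f:
                vert_faces[v].discard(f)
            faces.discard(f)
        n_faces -= len(removed)
        for f in changed:
            newf = tuple(keep if v == drop else v for v in f)
            if len(set(newf)) < 3 or newf in faces:
                for v in f:
                    vert_faces[v].discard(f)
                faces.discard(f)
                n_faces -= 1
                continue
            for v in f:
                vert_faces[v].discard(f)
            faces.discard(f)
            faces.add(newf)
            for v in newf:
                vert_faces.setdefault(v, set()).add(newf)
        quad[keep] = quad[keep] + quad[drop]
        vert_faces.pop(drop, None)
        version[keep] = ver(keep) + 1
        version[drop] = ver(drop) + 1
        for u in neighbours(keep):
            x, y = (u, keep) if u < keep else (keep, u)
            c, kp, dr = edge_cost(x, y)
            heapq.heappush(heap, (c, x, y, kp, dr, ver(x), ver(y)))
    if n_faces < 4:
        raise DegenerateGeometryError(
            "decimation fraction too small to keep a closed surface"
        )
    return TriMesh(nodes, np.array(sorted(faces)))


def reduce_surface(mesh: TriMesh, fraction: float) -> tuple[np.ndarray, TriMesh]:
    """Simplify a surface to ≈ ``fraction`` of its triangles.

    Returns (retained original node indices, decimated TriMesh).  Retained
    nodes are a subset of the input mesh's nodes by construction.
    """
    dec = decimate(mesh, fraction)
    return dec.used_nodes, dec


def _voxel_downsample(
    coords: np.ndarray, indices: np.ndarray, fraction: float, seed: int
) -> np.ndarray:
    """Seeded voxel-grid downsampling to ≈ fraction of ``indices``.

    One representative point per occupied voxel, chosen by a seeded RNG;
    the voxel size is bisected so the kept count lands near the target.
    """
    n = len(indices)
    target = max(1, int(round(fraction * n)))
    if target >= n:
        return indices
    pts = coords[indices]
    span = np.ptp(pts, axis=0).max()
    if span == 0:
        return indices[:target]

    def count(h):
        return len(np.unique(np.floor(pts / h).astype(np.int64), axis=0))

    lo, hi = span * 1e-3, span  # lo keeps ~everything, hi keeps ~1
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if count(mid) > target:
            lo = mid
        else:
            hi = mid
    h = 0.5 * (lo + hi)
    keys = np.floor(pts / h).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    rng = np.random.default_rng(seed)
    priority = rng.random(n)
    keep = []
    for g in range(inverse.max() + 1):
        members = np.nonzero(inverse == g)[0]
        keep.append(members[np.argmax(priority[members])])
    return indices[np.sort(np.array(keep))]


def coarsen_structure(points: PointSet, spec: CoarsenSpec) -> PointSet:
    """Layer-wise, shape-preserving coarse-graining of a point set.

    Every output point is one of the input points; the retained fraction is
    ≈ ``spec.fraction`` uniformly across surface layers and interior, so the
    coarse set still builds a proper alpha-shape surface.
    """
    if spec.fraction == 1.0:
        return points
    n = len(points)
    remaining = np.arange(n)
    retained: list[np.ndarray] = []
    for _layer in range(spec.n_layers):
        if len(remaining) < 4:
            break
        try:
            shape = build_alpha_shape(points.coords[remaining], spec.alpha)
        except DegenerateGeometryError:
            break
        surface = boundary_surface(shape)
        surf_local = surface.used_nodes
        if len(surf_local) == 0 or len(surf_local) == len(remaining):
            # nothing interior: decimate this last shell and stop
            kept_local, _ = reduce_surface(surface, spec.fraction)
            retained.append(remaining[kept_local])
            remaining = np.array([], dtype=int)
            break
        kept_local, _ = reduce_surface(surface, spec.fraction)
        retained.append(remaining[kept_local])
        interior_mask = np.ones(len(remaining), dtype=bool)
        interior_mask[surf_local] = False
        remaining = remaining[interior_mask]
    if len(remaining):
        retained.append(
            _voxel_downsample(points.coords, remaining, spec.fraction, spec.seed)
        )
    idx = np.unique(np.concatenate(retained)) if retained else np.arange(n)
    return points.take(idx)
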