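"""Finite-element stiffness and mass matrices for the alpha-shape solid.

The solid is treated as an isotropic, homogeneous linear-elastic material
described by Young's modulus E (kcal mol⁻¹ Å⁻³; ≈ 6.95 GPa per unit),
Poisson ratio ν, and a uniform mass density ρ (amu Å⁻³).  Elements are
4-node constant-strain tetrahedra; the mass matrix is the consistent
(non-diagonal) FEM mass, assembled per-node (N×N) and expanded to 3N×3N by
a Kronecker product with the 3×3 identity.

Node ordering of the global DOFs is x, y, z interleaved per node:
DOF(3·i + a) is axis a of node i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .alphashape import TetMesh
from .errors import DegenerateGeometryError
from .units import GPA_PER_KCAL_MOL_A3

__all__ = [
    "ElasticParams",
    "GlobalSystem",
    "lame_parameters",
    "element_stiffness",
    "element_mass",
    "assemble",
]


def lame_parameters(E: float, nu: float) -> tuple[float, float]:
    """Lamé parameters (λ, μ) from Young's modulus and Poisson ratio.

    λ = νE / ((1+ν)(1−2ν)),  μ = E / (2(1+ν)).
    """
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0.0 <= nu < 0.5:
        raise ValueError("Poisson ratio must satisfy 0 ≤ ν < 0.5 "
                         "(ν = 0.5 is the incompressible limit)")
    lam = nu * E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    return lam, mu


@dataclass
class ElasticParams:
    """Isotropic material: E (kcal mol⁻¹ Å⁻³), ν, density ρ (amu Å⁻³)."""

    E: float = 1.0
    nu: float = 0.3
    rho: float = 1.0

    def __post_init__(self) -> None:
        lame_parameters(self.E, self.nu)  # validates E, nu
        if self.rho <= 0:
            raise ValueError("density must be positive")

    @property
    def lam(self) -> float:
        return lame_parameters(self.E, self.nu)[0]

    @property
    def mu(self) -> float:
        return lame_parameters(self.E, self.nu)[1]

    @property
    def E_gpa(self) -> float:
        return self.E * GPA_PER_KCAL_MOL_A3

    @classmethod
    def for_mesh(cls, mesh: TetMesh, total_mass: float,
                 E: float = 1.0, nu: float = 0.3) -> "ElasticParams":
        """Uniform density chosen so ρ × shape volume = total node mass."""
        return cls(E=E, nu=nu, rho=total_mass / mesh.volume)


def _isotropic_c(lam: float, mu: float) -> np.ndarray:
    """6×6 elasticity matrix in Voigt order (xx, yy, zz, xy, yz, zx)."""
    c = np.zeros((6, 6))
    c[:3, :3] = lam
    c[np.arange(3), np.arange(3)] += 2.0 * mu
    c[3:, 3:] = mu * np.eye(3)
    return c


def _grads_and_volumes(coords: np.ndarray, tets: np.ndarray):
    """Shape-function gradients (T, 4, 3) and volumes (T,) for linear tets."""
    p = coords[tets]
    j = p[:, 1:] - p[:, :1]  # (T, 3, 3) rows are edge vectors
    det = np.linalg.det(j)
    vol = np.abs(det) / 6.0
    if np.any(vol <= 0):
        raise DegenerateGeometryError("zero-volume tetrahedron in mesh")
    jinv = np.linalg.inv(j)
    # barycentric gradients: rows 1..3 are ∇φ₁..∇φ₃ = (J⁻¹)ᵀ rows; φ₀ = 1−Σφᵢ
    g = np.empty((len(tets), 4, 3))
    g[:, 1:] = np.transpose(jinv, (0, 2, 1))
    g[:, 0] = -g[:, 1:].sum(axis=1)
    return g, vol


def _element_b(g: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices B (T, 6, 12) from gradients (T, 4, 3)."""
    t = len(g)
    b = np.zeros((t, 6, 12))
    for node in range(4):
        gx, gy, gz = g[:, node, 0], g[:, node, 1], g[:, node, 2]
        c = 3 * node
        b[:, 0, c + 0] = gx
        b[:, 1, c + 1] = gy
        b[:, 2, c + 2] = gz
        b[:, 3, c + 0] = gy
        b[:, 3, c + 1] = gx
        b[:, 4, c + 1] = gz
        b[:, 4, c + 2] = gy
        b[:, 5, c + 0] = gz
        b[:, 5, c + 2] = gx
    return b


def element_stiffness(tet_coords: np.ndarray, lam: float, mu: float) -> np.ndarray:
    """12×12 stiffness of one constant-strain tetrahedron: Kₑ = V·BᵀCB."""
    tet_coords = np.asarray(tet_coords, dtype=float).reshape(4, 3)
    g, vol = _grads_and_volumes(tet_coords, np.array([[0, 1, 2, 3]]))
    b = _element_b(g)[0]
    return vol[0] * b.T @ _isotropic_c(lam, mu) @ b


def element_mass(tet_coords: np.ndarray, rho: float) -> np.ndarray:
    """4×4 consistent mass (scalar-field block): ρV/20 · (1 + δᵢⱼ)."""
    tet_coords = np.asarray(tet_coords, dtype=float).reshape(4, 3)
    p1 = tet_coords[1:] - tet_coords[:1]
    vol = abs(np.linalg.det(p1)) / 6.0
    if vol <= 0:
        raise DegenerateGeometryError("zero-volume tetrahedron")
    return rho * vol / 20.0 * (np.ones((4, 4)) + np.eye(4))


@dataclass
class GlobalSystem:
    """Assembled global matrices: K (3N×3N stiffness), M (3N×3N mass)."""

    K: sp.csr_matrix
    M: sp.csr_matrix
    mesh: TetMesh
    params: ElasticParams

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    @property
    def n_dof(self) -> int:
        return 3 * self.mesh.n_nodes

    @property
    def total_mass(self) -> float:
        """ρ × volume, recovered as 1ᵀM1 over one axis' rows."""
        return float(self.M.sum()) / 3.0


def assemble(
    mesh: TetMesh,
    params: ElasticParams,
    lumped_mass: bool = False,
    warn_disconnected: bool = True,
) -> GlobalSystem:
    """Assemble sparse global K and M over all tetrahedra of ``mesh``.

    K scales linearly with E at fixed ν; M is independent of E.  With
    ``lumped_mass`` the consistent element mass is row-summed to a diagonal
    (useful for sensitivity checks; the consistent form is the default).
    """
    coords, tets = mesh.nodes, mesh.tets
    g, vol = _grads_and_volumes(coords, tets)
    b = _element_b(g)  # (T, 6, 12)
    c = _isotropic_c(params.lam, params.mu)
    ke = np.einsum("t,tiq,ij,tjp->tqp", vol, b, c, b, optimize=True)

    dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).reshape(-1)
    cols = np.tile(dof, (1, 12)).reshape(-1)
    n_dof = 3 * len(coords)
    K = sp.coo_matrix((ke.reshape(-1), (rows, cols)), shape=(n_dof, n_dof)).tocsr()

    # scalar-field consistent mass, then Kronecker expansion with I₃
    me = (params.rho * vol / 20.0)[:, None, None] * (np.ones((4, 4)) + np.eye(4))
    r4 = np.repeat(tets, 4, axis=1).reshape(-1)
    c4 = np.tile(tets, (1, 4)).reshape(-1)
    Mn = sp.coo_matrix(
        (me.reshape(-1), (r4, c4)), shape=(len(coords), len(coords))
    ).tocsr()
    if lumped_mass:
        Mn = sp.diags(np.asarray(Mn.sum(axis=1)).ravel())
    M = sp.kron(Mn, sp.identity(3), format="csr")

    if warn_disconnected:
        from scipy.sparse.csgraph import connected_components as _cc

        used = mesh.used_nodes
        adj = sp.coo_matrix(
            (np.ones(len(r4)), (r4, c4)), shape=(len(coords), len(coords))
        )
        ncomp, labels = _cc(adj + adj.T, directed=False)
        n_extra = ncomp - 1 - (len(coords) - len(used))  # isolated nodes aside
        if len(used) < len(coords) or n_extra > 0:
            import warnings

            warnings.warn(
                "mesh is not a single connected component; expect extra "
                "rigid-body (zero) modes downstream",
                stacklevel=2,
            )
    return GlobalSystem(K=K, M=M, mesh=mesh, params=params)
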