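"""Linear static response: point loads, clamped nodes, indentation stiffness.

Solves K_ff u_f = f_f − K_fc u_c on the free DOFs, with clamped and
prescribed-displacement DOFs eliminated.  Forces are in kcal mol⁻¹ Å⁻¹ and
displacements in Å; because K is linear in Young's modulus E, displacements
per unit force scale as 1/E and stiffness slopes scale as E.

The AFM indentation surrogate prescribes downward displacements on the
nodes inside a spherical tip's footprint and reads off the reaction-force
slope per unit indentation — the small-indentation linearization of a
rigid-sphere contact experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .alphashape import TetMesh
from .fem import ElasticParams, GlobalSystem, assemble
from .units import GPA_PER_KCAL_MOL_A3

__all__ = [
    "BoundaryCondition",
    "DeformationResult",
    "static_solve",
    "deformation_extents",
    "indentation_stiffness",
    "young_from_afm",
]

from .errors import UnderConstrainedError


@dataclass
class BoundaryCondition:
    """Clamped nodes, applied nodal forces, optional prescribed DOFs.

    ``fixed_nodes`` clamps all three DOFs of each listed node.
    ``forces`` maps node index → 3-vector (kcal mol⁻¹ Å⁻¹).
    ``prescribed`` maps a DOF index (3·node + axis) → displacement (Å).
    """

    fixed_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    forces: dict[int, np.ndarray] = field(default_factory=dict)
    prescribed: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=int)
        fixed = set(self.fixed_nodes.tolist())
        loaded = set(self.forces)
        if fixed & loaded:
            raise ValueError("fixed and loaded node sets must be disjoint")

    def constrained_dofs(self) -> tuple[np.ndarray, np.ndarray]:
        """(constrained DOF indices, their prescribed values), fixed first."""
        dofs = [3 * n + a for n in self.fixed_nodes for a in range(3)]
        vals = [0.0] * len(dofs)
        for dof, v in sorted(self.prescribed.items()):
            if dof in dofs:
                raise ValueError(f"DOF {dof} both clamped and prescribed")
            dofs.append(dof)
            vals.append(float(v))
        return np.asarray(dofs, dtype=int), np.asarray(vals)


@dataclass
class DeformationResult:
    """Solved displacements (N, 3) and reactions at constrained DOFs."""

    displacements: np.ndarray
    reactions: np.ndarray  # (n_constrained,) forces at constrained DOFs
    constrained_dofs: np.ndarray
    applied: np.ndarray  # full 3N applied force vector

    @property
    def u_flat(self) -> np.ndarray:
        return self.displacements.reshape(-1)

    def force_balance(self) -> np.ndarray:
        """Applied + reaction force totals per axis (≈ 0 at equilibrium)."""
        total = self.applied.reshape(-1, 3).sum(axis=0)
        react = np.zeros(3)
        for dof, r in zip(self.constrained_dofs, self.reactions):
            react[dof % 3] += r
        return total + react


def static_solve(system: GlobalSystem, bc: BoundaryCondition) -> DeformationResult:
    """Solve the constrained linear-elastic equilibrium problem."""
    K = system.K.tocsr()
    n_dof = K.shape[0]
    cdofs, cvals = bc.constrained_dofs()
    f = np.zeros(n_dof)
    for node, vec in bc.forces.items():
        f[3 * node: 3 * node + 3] = np.asarray(vec, dtype=float)
    free = np.setdiff1d(np.arange(n_dof), cdofs)
    u = np.zeros(n_dof)
    u[cdofs] = cvals
    Kff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, cdofs] @ cvals
    if len(free):
        try:
            lu = spla.splu(Kff)
            u[free] = lu.solve(rhs)
        except RuntimeError as exc:
            raise UnderConstrainedError(
                f"reduced stiffness is singular ({exc}); the free part of the "
                "mesh can still move rigidly — clamp at least one node per "
                "component"
            ) from exc
        resid = np.linalg.norm(Kff @ u[free] - rhs)
        scale = max(np.linalg.norm(rhs), 1e-300)
        if not np.all(np.isfinite(u)) or resid > 1e-6 * scale + 1e-8:
            raise UnderConstrainedError(
                "singular reduced stiffness: unconstrained rigid motion "
                "(translation/rotation) remains"
            )
    reactions = np.asarray(K[cdofs] @ u - f[cdofs]).ravel()
    return DeformationResult(
        displacements=u.reshape(-1, 3),
        reactions=reactions,
        constrained_dofs=cdofs,
        applied=f,
    )


def deformation_extents(result: DeformationResult, axis: int = 2):
    """Per-node |u_axis| and in-plane magnitude √(Σ other axes²).

    Returns a dict with per-node arrays and their maxima — the axial-vs-
    planar contrast used to compare solid and network mechanical response.
    """
    u = result.displacements
    ax = np.abs(u[:, axis])
    others = [a for a in range(3) if a != axis]
    plane = np.linalg.norm(u[:, others], axis=1)
    return {
        "extent_axis": ax,
        "extent_plane": plane,
        "max_axis": float(ax.max()),
        "max_plane": float(plane.max()),
    }


def indentation_stiffness(
    mesh: TetMesh,
    params: ElasticParams,
    tip_radius: float,
    tip_axis: int = 2,
    contact_depth_step: float = 1.0,
    base_fraction: float = 0.1,
    system: GlobalSystem | None = None,
) -> float:
    """Force–depth slope per unit Young's modulus (κ_cal, nm per GPa-unit).

    A rigid sphere of ``tip_radius`` (Å) is centred on the structure's axis
    through the centroid and lowered by ``contact_depth_step`` (Å) from
    first touch; nodes inside the lowered sphere get prescribed downward
    displacements equal to their penetration depth, nodes within
    ``base_fraction`` of the height from the bottom are clamped.  The total
    axial reaction on the contact set divided by the depth is the stiffness;
    normalized by E it is E-independent (K ∝ E) and converts to the
    nm-per-unit-E(GPa) scale used with AFM data.
    """
    coords = mesh.nodes[mesh.used_nodes]
    axis = tip_axis
    z = mesh.nodes[:, axis]
    zmin, zmax = coords[:, axis].min(), coords[:, axis].max()
    height = zmax - zmin
    centroid = coords.mean(axis=0)
    lateral = [a for a in range(3) if a != axis]
    rho = np.linalg.norm(mesh.nodes[:, lateral] - centroid[lateral], axis=1)

    used = set(mesh.used_nodes.tolist())
    # first-touch height: top of the surface inside the footprint
    in_foot = (rho < tip_radius) & np.isin(np.arange(len(z)), mesh.used_nodes)
    if not in_foot.any():
        raise ValueError("no nodes under the tip footprint; geometry error")
    depth = contact_depth_step
    z_sphere = zmax + tip_radius - depth  # centre height after indentation
    surf = z_sphere - np.sqrt(np.clip(tip_radius**2 - rho**2, 0.0, None))
    pen = z - surf
    contact = in_foot & (pen > 0)
    if not contact.any():
        raise ValueError("empty contact set at this depth/tip radius")

    base = np.array(
        [n for n in mesh.used_nodes if z[n] <= zmin + base_fraction * height],
        dtype=int,
    )
    prescribed = {
        3 * int(n) + axis: -float(pen[n]) for n in np.nonzero(contact)[0]
        if int(n) in used and int(n) not in set(base.tolist())
    }
    bc = BoundaryCondition(fixed_nodes=base, prescribed=prescribed)
    if system is None:
        system = assemble(mesh, params, warn_disconnected=False)
    res = static_solve(system, bc)
    # total axial reaction carried by the contact DOFs
    pres_dofs = np.array(sorted(prescribed), dtype=int)
    sel = np.isin(res.constrained_dofs, pres_dofs)
    force = float(np.abs(res.reactions[sel].sum()))
    k_per_e = force / depth / params.E  # Å per unit E (kcal/mol/Å³ scale)
    return k_per_e / 10.0  # nm per unit E expressed in GPa (nN/nm²)


def young_from_afm(kappa_cal: float, k_exp: float) -> float:
    """Young's modulus (GPa) from AFM stiffness: E = k_exp/κ_cal.

    ``k_exp`` in nN/nm, ``kappa_cal`` in nm per unit of E (GPa); the ratio
    is directly in GPa since nN/nm² = GPa.
    """
    if kappa_cal <= 0 or k_exp <= 0:
        raise ValueError("kappa_cal and k_exp must be positive")
    return k_exp / kappa_cal
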