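"""Anisotropic network model (ANM) baseline.

A minimal Cα mass-spring model for solid-vs-network comparisons: nodes
within a cutoff distance are joined by Hookean springs of constant γ
(kcal mol⁻¹ Å⁻²), and the Hessian of the ANM energy plays the role the FEM
stiffness plays in the solid model.  Masses are diagonal lumped residue
masses, unlike the solid model's consistent FEM mass matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .fem import ElasticParams, GlobalSystem
from .modes import RIGID_TOL, FluctuationProfile
from .pointset import PointSet
from .units import DEFAULT_TEMPERATURE, KB_KCAL_MOL_K

__all__ = ["AnmParams", "anm_hessian", "anm_system", "anm_msf"]


@dataclass
class AnmParams:
    """cutoff (Å) for contact detection, spring constant γ (kcal/mol/Å²)."""

    cutoff: float = 13.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.gamma <= 0:
            raise ValueError("cutoff and gamma must be positive")


def anm_hessian(points, params: AnmParams) -> sp.csr_matrix:
    """3N×3N ANM Hessian.

    For each contact pair (i, j) with |r_ij| ≤ cutoff the off-diagonal 3×3
    block is −γ·(r_ij r_ijᵀ)/|r_ij|²; diagonal blocks are minus the row
    sums.  Symmetric PSD with ≥ 6 zero modes (more if disconnected).
    """
    coords = points.coords if isinstance(points, PointSet) else np.asarray(points, float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two points")
    pairs = np.array(sorted(cKDTree(coords).query_pairs(params.cutoff)))
    if len(pairs) == 0:
        warnings.warn("no contacts within cutoff; Hessian is zero", stacklevel=2)
        return sp.csr_matrix((3 * n, 3 * n))
    contact_count = np.bincount(pairs.ravel(), minlength=n)
    if np.any(contact_count == 0):
        warnings.warn(
            f"{int((contact_count == 0).sum())} isolated node(s) without "
            "contacts; expect extra zero modes",
            stacklevel=2,
        )
    r = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    d2 = np.einsum("ij,ij->i", r, r)
    blocks = -params.gamma * np.einsum("pi,pj->pij", r, r) / d2[:, None, None]

    rows, cols, vals = [], [], []
    i3 = 3 * pairs[:, 0]
    j3 = 3 * pairs[:, 1]
    for a in range(3):
        for b in range(3):
            v = blocks[:, a, b]
            rows.extend([i3 + a, j3 + a, i3 + a, j3 + a])
            cols.extend([j3 + b, i3 + b, i3 + b, j3 + b])
            vals.extend([v, v, -v, -v])
    H = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, 3 * n),
    ).tocsr()
    return H


def anm_system(points: PointSet, params: AnmParams) -> GlobalSystem:
    """Package the ANM Hessian + lumped masses for the shared mode solver."""
    H = anm_hessian(points, params)
    M = sp.diags(np.repeat(points.masses, 3)).tocsr()
    mat = ElasticParams(E=params.gamma, nu=0.3,
                        rho=points.total_mass)  # rho unused for networks
    return GlobalSystem(K=H, M=M, mesh=_PointMesh(points), params=mat)


class _PointMesh:
    """Duck-typed stand-in so GlobalSystem can wrap a network of points."""

    def __init__(self, points: PointSet) -> None:
        self.nodes = points.coords
        self.n_nodes = len(points)
        self.volume = np.nan


def anm_msf(
    hessian: sp.spmatrix,
    gamma: float = 1.0,
    T: float = DEFAULT_TEMPERATURE,
    route: str = "pseudoinverse",
) -> FluctuationProfile:
    """Per-node mean-square fluctuation ⟨(ΔRᵢ)²⟩ = (k_BT/γ)·tr([H⁺]ᵢᵢ).

    ``hessian`` is the network Hessian at unit spring constant (mirroring
    the solid model, whose fluctuations use K at unit Young's modulus);
    ``gamma`` rescales the result, so doubling γ halves every msf.

    The pseudo-inverse deflates the rigid-body modes; more than 6 near-zero
    modes triggers a disconnected-network warning.  ``route='modal'`` sums
    v²/λ over non-rigid eigenpairs instead (same value, different path).
    """
    Hd = np.asarray(hessian.todense() if sp.issparse(hessian) else hessian)
    Hd = 0.5 * (Hd + Hd.T)
    w, u = sla.eigh(Hd)
    tol = RIGID_TOL * max(abs(w).max(), 1e-300)
    n_zero = int(np.sum(np.abs(w) < tol))
    if n_zero > 6:
        warnings.warn(
            f"{n_zero} near-zero modes (> 6): network is disconnected",
            stacklevel=2,
        )
    keep = w > tol
    if route == "pseudoinverse":
        hplus = (u[:, keep] / w[keep]) @ u[:, keep].T
        contrib = np.diag(hplus)
    elif route == "modal":
        contrib = (u[:, keep] ** 2 / w[keep]).sum(axis=1)
    else:
        raise ValueError("route must be 'pseudoinverse' or 'modal'")
    msf = KB_KCAL_MOL_K * T / gamma * contrib.reshape(-1, 3).sum(axis=1)
    return FluctuationProfile(msf=msf)
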