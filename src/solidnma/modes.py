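"""Normal modes, vibrational spectrum, fluctuations, calibration, overlaps.

Modes are solutions of the generalized eigenproblem K v = λ M v with the
FEM stiffness K and consistent mass M.  Eigenvectors are M-orthonormal
(vᵢᵀMvⱼ = δᵢⱼ); the mass-weighted modes qₖ = M^{1/2}vₖ form a Euclidean
orthonormal basis used for overlaps with conformational changes.

Unit bookkeeping: eigenvalues carry kcal mol⁻¹ amu⁻¹ Å⁻²;
ω[cm⁻¹] = 108.59·√λ (see :mod:`solidnma.units`).  Thermal mode amplitudes
follow equipartition: each mode's potential energy is k_BT/2, so
Aₖ² = k_BT/(E λₖ) when the system was assembled at unit Young's modulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial.transform import Rotation

from .errors import CalibrationError, SolverError
from .fem import GlobalSystem
from .units import DEFAULT_TEMPERATURE, KB_KCAL_MOL_K, WAVENUMBER_FACTOR

__all__ = [
    "ModeSet",
    "FluctuationProfile",
    "OverlapReport",
    "solve_modes",
    "to_wavenumbers",
    "spectrum_and_powerfit",
    "mean_square_fluctuations",
    "calibrate_young_modulus",
    "superpose",
    "displacement_vector",
    "overlap",
    "benchmark_metrics",
]

#: an eigenvalue below RIGID_TOL × (largest computed eigenvalue) is rigid.
RIGID_TOL = 1e-8


def to_wavenumbers(eigvals: np.ndarray) -> np.ndarray:
    """Convert eigenvalues (kcal mol⁻¹ amu⁻¹ Å⁻²) to wavenumbers (cm⁻¹)."""
    ev = np.asarray(eigvals, dtype=float)
    floor = -1e-6 * max(np.abs(ev).max(), 1.0)
    if np.any(ev < floor):
        raise SolverError("negative eigenvalue beyond numerical tolerance")
    return WAVENUMBER_FACTOR * np.sqrt(np.clip(ev, 0.0, None))


def _mass_sqrt(M: sp.spmatrix) -> np.ndarray | sp.spmatrix:
    """Symmetric square root of the mass matrix (sparse if M is diagonal)."""
    offdiag = M - sp.diags(M.diagonal())
    if offdiag.nnz == 0 or abs(offdiag).max() < 1e-300:
        return sp.diags(np.sqrt(M.diagonal()))
    w, u = sla.eigh(M.toarray())
    if w.min() <= 0:
        raise SolverError("mass matrix is not positive definite")
    return (u * np.sqrt(w)) @ u.T


@dataclass
class ModeSet:
    """Eigenpairs of K v = λ M v, sorted ascending, M-orthonormal."""

    eigvals: np.ndarray
    vecs: np.ndarray  # (3N, k), columns M-orthonormal
    M: sp.spmatrix
    n_rigid: int

    _msqrt: object = field(default=None, repr=False)

    @property
    def n_modes(self) -> int:
        return len(self.eigvals)

    @property
    def wavenumbers(self) -> np.ndarray:
        return to_wavenumbers(self.eigvals)

    @property
    def mass_weighted(self) -> np.ndarray:
        """qₖ = M^{1/2}vₖ (3N, k); Euclidean-orthonormal columns."""
        if self._msqrt is None:
            self._msqrt = _mass_sqrt(self.M)
        return np.asarray(self._msqrt @ self.vecs)

    def amplitudes(self, E: float = 1.0, T: float = DEFAULT_TEMPERATURE) -> np.ndarray:
        """Thermal amplitudes Aₖ = √(k_BT/(E λₖ)); inf for rigid modes."""
        with np.errstate(divide="ignore"):
            a2 = KB_KCAL_MOL_K * T / (E * self.eigvals)
        return np.sqrt(np.where(self.eigvals > 0, a2, np.inf))

    def nonrigid(self) -> "ModeSet":
        """The same set with rigid-body modes dropped."""
        return ModeSet(
            self.eigvals[self.n_rigid:], self.vecs[:, self.n_rigid:],
            self.M, 0, self._msqrt,
        )


def solve_modes(
    system: GlobalSystem | tuple,
    n_modes: int = 26,
    dense_cutoff: int = 1200,
    expected_rigid: int = 6,
) -> ModeSet:
    """Lowest ``n_modes`` solutions of K v = λ M v.

    Small systems (≤ ``dense_cutoff`` DOFs) use a dense generalized solver;
    larger ones use sparse shift-invert Lanczos with a small negative shift
    (K is PSD, so K − σM is positive definite for σ < 0).  Rigid-body modes
    are flagged by λ < 1e-8 × (largest computed λ); a connected free body
    has exactly 6, and a mismatch triggers a warning.
    """
    if isinstance(system, GlobalSystem):
        K, M = system.K, system.M
    else:
        K, M = system
    n_dof = K.shape[0]
    n_modes = min(n_modes, n_dof)
    if n_dof <= dense_cutoff or n_modes > n_dof - 2:
        w, v = sla.eigh(np.asarray(K.todense()), np.asarray(M.todense()))
        w, v = w[:n_modes], v[:, :n_modes]
    else:
        scale = K.diagonal().mean() / M.diagonal().mean()
        try:
            w, v = spla.eigsh(K, k=n_modes, M=M, sigma=-1e-3 * scale, which="LM")
        except Exception as exc:
            raise SolverError(
                f"sparse eigensolver failed ({exc}); try a different shift, "
                "more Lanczos vectors, or the dense path"
            ) from exc
        order = np.argsort(w)
        w, v = w[order], v[:, order]
    # enforce M-orthonormality sign convention for determinism
    for k in range(v.shape[1]):
        j = np.argmax(np.abs(v[:, k]))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    nrm = np.sqrt(np.einsum("ik,ik->k", v, np.asarray(M @ v)))
    v = v / nrm
    tol = RIGID_TOL * max(abs(w).max(), 1e-300)
    n_rigid = int(np.sum(w < tol))
    w = np.where(np.abs(w) < tol, np.clip(w, 0.0, None), w)
    if n_rigid != expected_rigid:
        warnings.warn(
            f"found {n_rigid} rigid-body modes, expected {expected_rigid} "
            "(disconnected mesh or over-tight tolerance?)",
            stacklevel=2,
        )
    return ModeSet(eigvals=w, vecs=v, M=M, n_rigid=n_rigid)


def spectrum_and_powerfit(
    modeset_or_wavenumbers, n_bins: int = 30
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Histogram of wavenumbers and the power-law exponent of G(ω).

    G(ω), the fraction of (non-rigid) modes below ω, is fitted as
    G ∝ ω^exponent by ordinary least squares in log–log space over the
    low-frequency half of the spectrum (ω below the median).
    """
    if isinstance(modeset_or_wavenumbers, ModeSet):
        ms = modeset_or_wavenumbers
        omega = ms.wavenumbers[ms.n_rigid:]
    else:
        omega = np.asarray(modeset_or_wavenumbers, dtype=float)
    omega = np.sort(omega[omega > 0])
    if len(omega) < 20:
        raise CalibrationError("need at least 20 non-rigid modes for a fit")
    hist = np.histogram(omega, bins=n_bins)
    g = np.arange(1, len(omega) + 1) / len(omega)
    low = omega <= np.median(omega)
    x, y = np.log(omega[low]), np.log(g[low])
    slope = np.polyfit(x, y, 1)[0]
    return hist, float(slope)


@dataclass
class FluctuationProfile:
    """Per-node mean-square fluctuations and derived B-factors."""

    msf: np.ndarray  # Å²

    @property
    def bfactors(self) -> np.ndarray:
        """B = 8π²/3 · ⟨(ΔR)²⟩ (Å²)."""
        return (8.0 * np.pi**2 / 3.0) * self.msf

    def pearson(self, experimental_b: np.ndarray) -> float:
        return float(np.corrcoef(self.bfactors, experimental_b)[0, 1])


def mean_square_fluctuations(
    system: GlobalSystem,
    modeset: ModeSet | None = None,
    E: float = 1.0,
    T: float = DEFAULT_TEMPERATURE,
    route: str = "modal",
) -> FluctuationProfile:
    """Thermal mean-square fluctuation per node.

    ``route='modal'``: ⟨(ΔRᵢ)²⟩ = (k_BT/E) Σ_k |v_{k,i}|²/λ_k over non-rigid
    modes of ``modeset`` (computed at unit E; the 1/E factor rescales).

    ``route='pseudoinverse'``: the same quantity from the i-th 3×3 diagonal
    block trace of M^{-1/2} K_m⁺ M^{-1/2}, with K_m = M^{-1/2} K M^{-1/2}
    and rigid modes deflated — a dense, mode-free cross-check.
    """
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    kbt = KB_KCAL_MOL_K * T
    n_dof = system.K.shape[0]
    if route == "modal":
        if modeset is None:
            modeset = solve_modes(system, n_modes=n_dof)
        nz = modeset.nonrigid()
        contrib = (nz.vecs**2 / nz.eigvals).sum(axis=1)  # Σ v²/λ per DOF
    elif route == "pseudoinverse":
        msqrt = _mass_sqrt(system.M)
        minv_sqrt = (
            sp.diags(1.0 / np.sqrt(system.M.diagonal()))
            if sp.issparse(msqrt)
            else np.linalg.inv(msqrt)
        )
        km = np.asarray(minv_sqrt @ system.K @ minv_sqrt)
        km = 0.5 * (km + km.T)
        w, u = sla.eigh(km)
        tol = RIGID_TOL * abs(w).max()
        keep = w > tol
        kplus = (u[:, keep] / w[keep]) @ u[:, keep].T
        cov = np.asarray(minv_sqrt @ kplus @ minv_sqrt)
        contrib = np.diag(cov)
    else:
        raise ValueError("route must be 'modal' or 'pseudoinverse'")
    msf = kbt / E * contrib.reshape(-1, 3).sum(axis=1)
    return FluctuationProfile(msf=msf)


def calibrate_young_modulus(
    msf_unit_E: np.ndarray | FluctuationProfile,
    experimental_b: np.ndarray,
) -> tuple[float, float]:
    """Least-squares Young's modulus from experimental B-factors.

    With P = (8π²/3)·msf computed at E = 1, the prediction at modulus E is
    P/E; the optimal scale is 1/E = (P·B)/(P·P).  Returns (E, Pearson r of
    predicted vs experimental B, which is scale-invariant).
    """
    if isinstance(msf_unit_E, FluctuationProfile):
        p = msf_unit_E.bfactors
    else:
        p = (8.0 * np.pi**2 / 3.0) * np.asarray(msf_unit_E, dtype=float)
    b = np.asarray(experimental_b, dtype=float)
    if b.shape != p.shape:
        raise CalibrationError("B-factor vector length mismatch")
    if np.std(b) == 0 or np.std(p) == 0:
        raise CalibrationError("zero-variance B-factor column")
    scale = float(p @ b) / float(p @ p)  # = 1/E
    if scale <= 0:
        raise CalibrationError("anti-correlated B-factors give non-positive E")
    return 1.0 / scale, float(np.corrcoef(p, b)[0, 1])


def superpose(ref: np.ndarray, mobile: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of ``mobile`` onto ``ref`` (N, 3)."""
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    rc, mc = ref.mean(axis=0), mobile.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot.apply(mobile - mc) + rc


def displacement_vector(ref: np.ndarray, mobile: np.ndarray) -> np.ndarray:
    """3N displacement from ``ref`` to superposed ``mobile``."""
    return (superpose(ref, mobile) - np.asarray(ref, dtype=float)).reshape(-1)


@dataclass
class OverlapReport:
    """Per-mode overlaps of a conformational change with the mode basis.

    Modes are indexed from the first non-rigid mode as 1.  ``delta`` maps m
    to the cumulative overlap √(Σ_{k≤m} O_k²) over the first m modes;
    ``n_sigma90`` is the smallest m whose cumulative squared overlap reaches
    0.90 (None if not reached within the computed modes).
    """

    overlaps: np.ndarray

    @property
    def alpha123(self) -> np.ndarray:
        """The three largest |O| values, descending."""
        a = np.sort(np.abs(self.overlaps))[::-1]
        return a[:3]

    @property
    def delta(self) -> dict[int, float]:
        c = np.sqrt(np.cumsum(self.overlaps**2))
        return {m: float(c[m - 1]) for m in (3, 5, 10) if m <= len(c)}

    @property
    def n_alpha1(self) -> int:
        return int(np.argmax(np.abs(self.overlaps))) + 1

    @property
    def n_sigma90(self) -> int | None:
        c = np.cumsum(self.overlaps**2)
        hits = np.nonzero(c >= 0.90)[0]
        return int(hits[0]) + 1 if len(hits) else None


def overlap(d: np.ndarray, modeset: ModeSet) -> OverlapReport:
    """Overlaps O_k = d·q_k/‖d‖ with the mass-weighted non-rigid modes."""
    d = np.asarray(d, dtype=float).reshape(-1)
    if d.shape[0] != modeset.vecs.shape[0]:
        raise ValueError(
            f"displacement has {d.shape[0]} DOFs, modes have "
            f"{modeset.vecs.shape[0]} (node-count/alignment mismatch)"
        )
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("zero displacement vector")
    q = modeset.mass_weighted[:, modeset.n_rigid:]
    return OverlapReport(overlaps=(d @ q) / nrm)


def benchmark_metrics(reports: list[OverlapReport]):
    """Mean overlap metrics over a set of conformational-change cases."""
    import pandas as pd

    if not reports:
        raise ValueError("need at least one overlap report")
    rows = []
    for r in reports:
        a = r.alpha123
        row = {"alpha1": a[0], "alpha2": a[1] if len(a) > 1 else np.nan,
               "alpha3": a[2] if len(a) > 2 else np.nan}
        row.update({f"delta{m}": v for m, v in r.delta.items()})
        row["N_alpha1"] = r.n_alpha1
        row["N_sigma90"] = np.nan if r.n_sigma90 is None else r.n_sigma90
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.mean().to_frame(name="mean").T
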