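"""Deterministic synthetic structures and density maps.

Everything downstream — alpha shapes, FEM assembly, modes, mechanics,
coarse-graining, density thresholding — is exercised on these generators,
which have known closed-form geometry (lattice volumes, bar lengths, sphere
volumes) so tests can compare against analytic answers without downloads.

Default point mass is 110 amu (mean amino-acid residue mass) so frequency
magnitudes come out protein-like.
"""

from __future__ import annotations

import numpy as np

from .pointset import DensityGrid, PointSet

__all__ = [
    "make_lattice",
    "make_bar",
    "make_shell",
    "make_helix",
    "make_sphere_map",
]

DEFAULT_MASS = 110.0


def _grid(nx: int, ny: int, nz: int, spacing: float) -> np.ndarray:
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    return spacing * np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)


def make_lattice(n: int, spacing: float = 1.0, mass: float = DEFAULT_MASS) -> PointSet:
    """n³ points on a cubic grid; full alpha-shape volume (n−1)³·spacing³."""
    if n < 2:
        raise ValueError("n must be ≥ 2")
    coords = _grid(n, n, n, spacing)
    return PointSet(coords=coords, masses=np.full(len(coords), mass))


def make_bar(
    nx: int, ny: int, nz: int, spacing: float = 1.0, mass: float = DEFAULT_MASS
) -> PointSet:
    """Rectangular lattice bar of length L = (nx−1)·spacing along x."""
    coords = _grid(nx, ny, nz, spacing)
    return PointSet(coords=coords, masses=np.full(len(coords), mass))


def make_shell(
    outer_radius: float,
    thickness: float,
    spacing: float = 1.0,
    hemisphere: bool = False,
    mass: float = DEFAULT_MASS,
) -> PointSet:
    """Spherical (or hemispherical) shell cut from a cubic lattice."""
    r_out, r_in = outer_radius, outer_radius - thickness
    n = int(np.ceil(2 * r_out / spacing)) + 1
    coords = _grid(n, n, n, spacing) - r_out
    r = np.linalg.norm(coords, axis=1)
    keep = (r <= r_out) & (r >= r_in)
    if hemisphere:
        keep &= coords[:, 2] >= -spacing / 2
    coords = coords[keep]
    return PointSet(coords=coords, masses=np.full(len(coords), mass))


def make_helix(
    n_residues: int = 60,
    rise: float = 1.5,
    radius: float = 2.3,
    turn_deg: float = 100.0,
    supercoil_radius: float = 8.0,
    mass: float = DEFAULT_MASS,
    seed: int | None = None,
) -> PointSet:
    """A Cα-like helical trace, optionally perturbed; protein-like spacing.

    With a supercoil the trace bends around a larger circle so the point
    cloud is globular enough to build a sensible alpha shape.
    """
    t = np.arange(n_residues)
    ang = np.deg2rad(turn_deg) * t
    local = np.column_stack([
        radius * np.cos(ang), radius * np.sin(ang), rise * t
    ])
    if supercoil_radius > 0:
        height = rise * n_residues
        phi = local[:, 2] / height * np.pi
        x = (supercoil_radius + local[:, 0]) * np.cos(phi)
        y = (supercoil_radius + local[:, 0]) * np.sin(phi)
        coords = np.column_stack([x, y, local[:, 1]])
    else:
        coords = local
    if seed is not None:
        coords = coords + np.random.default_rng(seed).normal(0, 0.05, coords.shape)
    return PointSet(coords=coords, masses=np.full(n_residues, mass))


def make_sphere_map(
    radius: float,
    voxel: float = 1.0,
    noise_seed: int | None = None,
    blur_sigma: float = 0.0,
    pad: int = 2,
) -> DensityGrid:
    """Binary sphere density (1 inside, 0 outside), optional Gaussian blur.

    The sphere is centred in the grid; grid samples sit at voxel centres.
    """
    if radius <= 2 * voxel:
        raise ValueError("radius must exceed two voxel spacings")
    half = int(np.ceil(radius / voxel)) + pad
    n = 2 * half + 1
    ax = (np.arange(n) - half) * voxel
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    values = (x**2 + y**2 + z**2 <= radius**2).astype(float)
    if blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        values = gaussian_filter(values, sigma=blur_sigma / voxel)
    if noise_seed is not None:
        values = values + np.random.default_rng(noise_seed).normal(
            0, 0.01, values.shape
        )
    origin = -half * voxel * np.ones(3)
    return DensityGrid(origin=origin, spacing=np.full(3, voxel), values=values)
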