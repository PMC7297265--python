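"""Core containers: labelled point sets and density grids.

A :class:`PointSet` holds the nodes of every solid model built by this
package — Cα atoms, all heavy atoms, or thresholded density voxels — together
with per-point masses (amu) and, when available, experimental B-factors (Å²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, EmptySelectionError


@dataclass
class PointSet:
    """Labelled 3-D points with masses and optional B-factors.

    Parameters
    ----------
    coords : (N, 3) float array, Å
    masses : (N,) float array, amu; defaults to 110 amu per point (mean
        amino-acid residue mass) when not given.
    labels : sequence of per-point source tags (chain/residue or voxel index).
    bfactors : optional (N,) float array, Å².
    """

    coords: np.ndarray
    masses: np.ndarray | None = None
    labels: list[str] | None = None
    bfactors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        if self.masses is None:
            self.masses = np.full(n, 110.0)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n,):
            raise ValueError("masses must be a length-N vector")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.labels is None:
            self.labels = [str(i) for i in range(n)]
        if self.bfactors is not None:
            self.bfactors = np.asarray(self.bfactors, dtype=float)
            if self.bfactors.shape != (n,):
                raise ValueError("bfactors must be a length-N vector")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def deduplicate(self, decimals: int = 6) -> "PointSet":
        """Drop points that coincide exactly (after rounding), keeping the first."""
        _, idx = np.unique(
            np.round(self.coords, decimals), axis=0, return_index=True
        )
        idx = np.sort(idx)
        return self.take(idx)

    def take(self, indices: np.ndarray) -> "PointSet":
        """Sub-select points by index, preserving order of ``indices``."""
        indices = np.asarray(indices, dtype=int)
        return PointSet(
            coords=self.coords[indices],
            masses=self.masses[indices],
            labels=[self.labels[i] for i in indices],
            bfactors=None if self.bfactors is None else self.bfactors[indices],
        )


@dataclass
class DensityGrid:
    """A scalar density sampled on a regular 3-D grid (cryo-EM map).

    ``values[i, j, k]`` is the density at world position
    ``origin + (i, j, k) * spacing`` (x, y, z axis order).
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("values must be a 3-D array, ≥ 2 voxels per axis")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (Å) of grid indices ``idx`` (..., 3)."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def points_above(
        self,
        threshold: float,
        mass_per_point: float = 110.0,
        total_mass: float | None = None,
    ) -> PointSet:
        """Voxels with density strictly above ``threshold`` as a PointSet.

        Point masses are proportional to voxel density; the proportionality
        constant is set so the total equals ``total_mass`` when given, and
        ``mass_per_point`` × (number of kept voxels) otherwise.
        """
        if not np.isfinite(threshold):
            raise ValueError("threshold must be finite")
        idx = np.argwhere(self.values > threshold)
        if len(idx) == 0:
            raise EmptySelectionError(
                f"no voxel has density above {threshold}"
            )
        vals = self.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        target = total_mass if total_mass is not None else mass_per_point * len(idx)
        weights = vals * self.voxel_volume
        if weights.sum() <= 0:
            raise DegenerateGeometryError("non-positive total density weight")
        masses = weights * (target / weights.sum())
        labels = [f"voxel:{i},{j},{k}" for i, j, k in idx]
        return PointSet(
            coords=self.index_to_world(idx),
            masses=masses,
            labels=labels,
        )
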