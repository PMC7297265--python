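"""Cryo-EM density maps (MRC/CCP4 2014) as regular grids.

Reading normalizes the axis order to x, y, z regardless of the MAPC/MAPR/
MAPS permutation in the header; the world origin comes from the MRC ORIGIN
record when set and from NXSTART/NYSTART/NZSTART otherwise.  Writing is
provided so synthetic fixtures can round-trip through real files.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import EmptySelectionError, FormatError
from .pointset import DensityGrid, PointSet

__all__ = ["read_density", "write_density", "points_from_density"]


def read_density(path) -> DensityGrid:
    """Read an MRC/CCP4 map into a :class:`DensityGrid` (x, y, z order)."""
    import gemmi

    try:
        m = gemmi.read_ccp4_map(str(path))
        m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read density map {path}: {exc}") from exc
    values = np.array(m.grid, copy=True, dtype=float)
    cell = m.grid.unit_cell
    shape = np.array(values.shape, dtype=float)
    spacing = np.array([cell.a, cell.b, cell.c]) / shape
    origin = np.array([m.header_float(i) for i in (50, 51, 52)])
    if np.allclose(origin, 0.0):
        nstart = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=float)
        origin = nstart * spacing
    return DensityGrid(origin=origin, spacing=spacing, values=values)


def write_density(grid: DensityGrid, path) -> None:
    """Write a :class:`DensityGrid` as an MRC/CCP4 2014 map."""
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    shape = grid.values.shape
    m.grid.unit_cell = gemmi.UnitCell(
        shape[0] * grid.spacing[0],
        shape[1] * grid.spacing[1],
        shape[2] * grid.spacing[2],
        90.0, 90.0, 90.0,
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), grid.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


def points_from_density(
    grid: DensityGrid,
    threshold: float,
    mass_per_point: float = 110.0,
    total_mass: float | None = None,
) -> PointSet:
    """One node per voxel above ``threshold``, at voxel world coordinates.

    Node masses are proportional to voxel density, scaled so the total mass
    is ``total_mass`` when given and ``mass_per_point`` (default 110 amu,
    a mean residue mass) per kept voxel otherwise.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return grid.points_above(
        threshold, mass_per_point=mass_per_point, total_mass=total_mass
    )
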