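"""Output writers: NMD mode files, multi-model PDB trajectories, CSV tables.

The NMD dialect is the one read by the VMD/ProDy Normal Mode Wizard:
whitespace-separated ``coordinates``, ``mode <index> <scale> <vector>``
lines, plus ``names``/``resids`` metadata; a ``frequencies`` line (cm⁻¹)
is added for completeness and ignored by viewers that do not know it.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError
from .modes import ModeSet
from .pointset import PointSet

__all__ = ["write_modes", "read_nmd", "write_points_pdb"]


def write_modes(
    points: PointSet,
    modeset: ModeSet,
    path,
    fmt: str = "nmd",
    mode_indices: list[int] | None = None,
    amplitude: float = 1.0,
    n_frames: int = 21,
) -> None:
    """Write modes as NMD, a multi-model PDB trajectory, or CSV.

    * ``nmd`` — coordinates, per-mode eigenvectors and wavenumbers;
    * ``pdb`` — one oscillation period of the first selected mode sampled
      over ``n_frames`` models at the given amplitude (first and last frames
      equal the input coordinates);
    * ``csv`` — eigenvalues and wavenumbers of all modes.
    """
    fmt = fmt.lower()
    k = modeset.n_modes
    indices = list(range(modeset.n_rigid, k)) if mode_indices is None else mode_indices
    for i in indices:
        if not 0 <= i < k:
            raise IndexError(f"mode index {i} out of range 0..{k - 1}")
    if fmt == "nmd":
        _write_nmd(points, modeset, path, indices)
    elif fmt == "pdb":
        _write_traj_pdb(points, modeset, path, indices[0], amplitude, n_frames)
    elif fmt == "csv":
        import pandas as pd

        pd.DataFrame(
            {
                "mode": np.arange(k),
                "eigenvalue": modeset.eigvals,
                "wavenumber_cm1": modeset.wavenumbers,
                "rigid": np.arange(k) < modeset.n_rigid,
            }
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown mode output format {fmt!r}")


def _write_nmd(points, modeset, path, indices) -> None:
    wav = modeset.wavenumbers
    with open(path, "w") as f:
        f.write("title solidnma modes\n")
        f.write("names " + " ".join(str(l).replace(" ", "_") for l in points.labels) + "\n")
        f.write("coordinates " + " ".join(f"{x:.3f}" for x in points.coords.ravel()) + "\n")
        f.write("frequencies " + " ".join(f"{wav[i]:.6f}" for i in indices) + "\n")
        for i in indices:
            vec = modeset.vecs[:, i]
            f.write(
                f"mode {i + 1} 1.0 " + " ".join(f"{v:.6e}" for v in vec) + "\n"
            )


def read_nmd(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse an NMD file → (coords (N,3), modes (3N,k), wavenumbers (k,))."""
    coords, vecs, freqs = None, [], []
    with open(path) as f:
        for line in f:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "coordinates":
                coords = np.array(parts[1:], dtype=float).reshape(-1, 3)
            elif parts[0] == "frequencies":
                freqs = [float(v) for v in parts[1:]]
            elif parts[0] == "mode":
                vecs.append(np.array(parts[3:], dtype=float))
    if coords is None or not vecs:
        raise FormatError(f"{path} is not a parseable NMD file")
    return coords, np.column_stack(vecs), np.array(freqs)


def _pdb_atom_line(serial, name, resn, chain, resi, xyz, occ=1.0, b=0.0) -> str:
    name = name[:4]
    pad = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {pad}{'':1s}{resn:>3s} {chain:1s}{resi:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {'C':>2s}\n"
    )


def _write_traj_pdb(points, modeset, path, mode_index, amplitude, n_frames) -> None:
    vec = modeset.vecs[:, mode_index].reshape(-1, 3)
    phases = np.linspace(0.0, 2.0 * np.pi, n_frames)
    with open(path, "w") as f:
        for m, ph in enumerate(phases, start=1):
            f.write(f"MODEL     {m:>4d}\n")
            frame = points.coords + amplitude * np.sin(ph) * vec
            for i, xyz in enumerate(frame):
                b = 0.0 if points.bfactors is None else points.bfactors[i]
                f.write(_pdb_atom_line(
                    (i % 99999) + 1, "CA", "GLY", "A", (i % 9999) + 1, xyz, b=b
                ))
            f.write("ENDMDL\n")
        f.write("END\n")


def write_points_pdb(points: PointSet, path) -> None:
    """Write a point set as CA pseudo-atom records (for viewers/round-trips)."""
    with open(path, "w") as f:
        for i, xyz in enumerate(points.coords):
            b = 0.0 if points.bfactors is None else points.bfactors[i]
            f.write(_pdb_atom_line(
                (i % 99999) + 1, "CA", "GLY", "A", (i % 9999) + 1, xyz, b=b
            ))
        f.write("END\n")
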