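"""Atomic structures: PDB/mmCIF reading, node selection, assembly expansion.

Parsing is delegated to gemmi; this module flattens the hierarchy into a
plain :class:`Structure` (arrays of atoms plus biological-assembly
operators) and turns selections of it into the :class:`PointSet` nodes that
the solid model is built on.

Node-mass conventions: Cα nodes carry their residue's total average mass
(amu); all-heavy-atom nodes carry atomic masses.  Hydrogens and waters are
always excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyStructureError, FormatError, TooFewNodesError
from .pointset import PointSet

# Average residue masses (amu) of the 20 standard amino acids (residue =
# amino acid minus water, i.e. the mass the residue contributes to a chain).
RESIDUE_MASSES = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09,
    "CYS": 103.14, "GLN": 128.13, "GLU": 129.12, "GLY": 57.05,
    "HIS": 137.14, "ILE": 113.16, "LEU": 113.16, "LYS": 128.17,
    "MET": 131.19, "PHE": 147.18, "PRO": 97.12, "SER": 87.08,
    "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
}
DEFAULT_RESIDUE_MASS = 110.0


@dataclass
class Structure:
    """Flattened atom table plus biological-assembly operators.

    ``transforms`` is a list of (R, t) pairs: 3×3 rotations (orthonormal to
    1e-6) and translation 3-vectors, typically from REMARK 350.
    """

    chain: list[str]
    resi: np.ndarray
    resn: list[str]
    name: list[str]
    element: list[str]
    coords: np.ndarray
    occ: np.ndarray
    bfac: np.ndarray
    transforms: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        self.resi = np.asarray(self.resi, dtype=int)
        self.occ = np.asarray(self.occ, dtype=float)
        self.bfac = np.asarray(self.bfac, dtype=float)
        for rot, _ in self.transforms:
            if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
                raise ValueError("assembly rotation is not orthonormal")

    def __len__(self) -> int:
        return len(self.coords)

    def take(self, idx: np.ndarray) -> "Structure":
        idx = np.asarray(idx, dtype=int)
        return Structure(
            chain=[self.chain[i] for i in idx],
            resi=self.resi[idx],
            resn=[self.resn[i] for i in idx],
            name=[self.name[i] for i in idx],
            element=[self.element[i] for i in idx],
            coords=self.coords[idx],
            occ=self.occ[idx],
            bfac=self.bfac[idx],
            transforms=list(self.transforms),
        )

    def n_residues(self) -> int:
        return len({(c, int(r)) for c, r in zip(self.chain, self.resi)})

    def exclude_residues(
        self, chain: str, start: int, stop: int
    ) -> "Structure":
        """Drop residues ``start``..``stop`` (inclusive) of one chain.

        Exposed for removing disconnected segments (e.g. an unresolved
        N-terminal hairpin) explicitly rather than by auto-detection.
        """
        keep = [
            i for i in range(len(self))
            if not (self.chain[i] == chain and start <= self.resi[i] <= stop)
        ]
        return self.take(np.array(keep, dtype=int))


_WATERS = {"HOH", "WAT", "DOD"}


def read_structure(
    path, model_index: int = 0, altloc_policy: str = "highest-occupancy"
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Keeps the selected model's non-hydrogen, non-water atoms, preserves the
    B-factor column, and records biological-assembly operators (REMARK 350 /
    assembly category) when present.  ``altloc_policy`` is currently
    'highest-occupancy': one atom per alternate-location group, highest
    occupancy winning, ties broken alphabetically.
    """
    import gemmi

    if altloc_policy != "highest-occupancy":
        raise ValueError("only the 'highest-occupancy' altloc policy exists")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0 or model_index >= len(st):
        raise EmptyStructureError(f"no model {model_index} in {path}")
    model = st[model_index]

    best: dict[tuple, tuple] = {}  # altloc group -> (occ, altloc, atom record)
    order: list[tuple] = []
    for ch in model:
        for res in ch:
            if res.name in _WATERS:
                continue
            for at in res:
                if at.element.is_hydrogen:
                    continue
                key = (ch.name, res.seqid.num, res.seqid.icode, res.name, at.name)
                rec = (
                    ch.name, res.seqid.num, res.name, at.name,
                    at.element.name, (at.pos.x, at.pos.y, at.pos.z),
                    at.occ, at.b_iso,
                )
                # higher occupancy wins; tie -> alphabetically first altloc
                rank = (-at.occ, at.altloc or "")
                if key not in best:
                    best[key] = (rank, rec)
                    order.append(key)
                elif rank < best[key][0]:
                    best[key] = (rank, rec)
    if not order:
        raise EmptyStructureError(f"model {model_index} of {path} has no atoms")
    recs = [best[k][1] for k in order]
    transforms = []
    for asm in st.assemblies:
        for gen in asm.generators:
            for op in gen.operators:
                t = op.transform
                transforms.append(
                    (np.array(t.mat.tolist()), np.array(t.vec.tolist()))
                )
        break  # first biological assembly only
    return Structure(
        chain=[r[0] for r in recs],
        resi=np.array([r[1] for r in recs]),
        resn=[r[2] for r in recs],
        name=[r[3] for r in recs],
        element=[r[4] for r in recs],
        coords=np.array([r[5] for r in recs]),
        occ=np.array([r[6] for r in recs]),
        bfac=np.array([r[7] for r in recs]),
        transforms=transforms,
    )


def apply_assembly(structure: Structure) -> Structure:
    """Replicate the atoms under every assembly operator.

    Chain ids are suffixed with the copy number; with k operators the atom
    count is exactly k times the input's.  Without operators the structure
    is returned unchanged with a warning.
    """
    if not structure.transforms:
        warnings.warn("structure has no assembly operators; returning as-is",
                      stacklevel=2)
        return structure
    chains, resi, resn, name, elem, coords, occ, bfac = [], [], [], [], [], [], [], []
    for k, (rot, trans) in enumerate(structure.transforms, start=1):
        chains.extend(f"{c}_{k}" for c in structure.chain)
        resi.append(structure.resi)
        resn.extend(structure.resn)
        name.extend(structure.name)
        elem.extend(structure.element)
        coords.append(structure.coords @ rot.T + trans)
        occ.append(structure.occ)
        bfac.append(structure.bfac)
    return Structure(
        chain=chains,
        resi=np.concatenate(resi),
        resn=resn,
        name=name,
        element=elem,
        coords=np.vstack(coords),
        occ=np.concatenate(occ),
        bfac=np.concatenate(bfac),
        transforms=[],
    )


def select_nodes(
    structure: Structure,
    selector: str = "calpha",
    k: int = 1,
    min_points: int = 4,
) -> PointSet:
    """Turn a structure selection into model nodes.

    selector:
      * ``'calpha'`` — one node per residue at its Cα, mass = residue mass;
      * ``'every-kth-calpha'`` — every k-th Cα per chain (residues 1, 1+k, …
        in chain order), mass = residue mass;
      * ``'all-heavy'`` — every non-hydrogen atom, atomic masses.

    B-factors are copied from the selected atoms.  Selections smaller than
    ``min_points`` (default 4, the minimum for a tetrahedral solid) raise;
    pass ``min_points=1`` to allow sub-mesh selections.
    """
    import gemmi

    if len(structure) == 0:
        raise EmptyStructureError("empty structure")
    if selector in ("calpha", "every-kth-calpha"):
        idx = [
            i for i in range(len(structure))
            if structure.name[i] == "CA" and structure.element[i] == "C"
        ]
        if selector == "every-kth-calpha":
            if k < 1:
                raise ValueError("stride k must be ≥ 1")
            strided = []
            by_chain: dict[str, int] = {}
            for i in idx:
                c = structure.chain[i]
                pos = by_chain.get(c, 0)
                if pos % k == 0:
                    strided.append(i)
                by_chain[c] = pos + 1
            idx = strided
        masses = np.array([
            RESIDUE_MASSES.get(structure.resn[i], DEFAULT_RESIDUE_MASS)
            for i in idx
        ])
    elif selector == "all-heavy":
        idx = list(range(len(structure)))
        masses = np.array([
            gemmi.Element(structure.element[i]).weight for i in idx
        ])
    else:
        raise ValueError(f"unknown selector {selector!r}")
    if len(idx) < min_points:
        raise TooFewNodesError(
            f"selector {selector!r} keeps {len(idx)} points; need ≥ "
            f"{min_points} (a tetrahedral solid needs 4)"
        )
    labels = [
        f"{structure.chain[i]}:{structure.resi[i]}:{structure.name[i]}"
        for i in idx
    ]
    idx = np.asarray(idx, dtype=int)
    return PointSet(
        coords=structure.coords[idx],
        masses=masses,
        labels=labels,
        bfactors=structure.bfac[idx],
    )
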