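"""Flat atom-array container for receptor structures plus PDB I/O.

The container mirrors the usual atom-array design (one numpy column per
attribute) so that energy and scoring code can stay fully vectorized.
PDB parsing/writing is delegated to biotite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Structure:
    """A set of atoms belonging to one polypeptide chain (or a ligand).

    Attributes
    ----------
    coords : (n, 3) float array, Angstrom
    atom_names : (n,) str array, PDB atom names
    elements : (n,) str array, element symbols
    res_seq : (n,) int array, residue sequence numbers
    res_names : (n,) str array, three-letter residue names
    chain_ids : (n,) str array
    """

    coords: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    res_seq: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.res_seq = np.asarray(self.res_seq, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        if self.chain_ids is None:
            self.chain_ids = np.full(len(self.coords), "A", dtype=object)
        else:
            self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        n = len(self.coords)
        for name in ("atom_names", "elements", "res_seq", "res_names", "chain_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match coords ({n})")

    def __len__(self) -> int:
        return len(self.coords)

    def copy(self) -> "Structure":
        return Structure(
            self.coords.copy(),
            self.atom_names.copy(),
            self.elements.copy(),
            self.res_seq.copy(),
            self.res_names.copy(),
            self.chain_ids.copy(),
        )

    def select(self, mask) -> "Structure":
        mask = np.asarray(mask)
        return Structure(
            self.coords[mask],
            self.atom_names[mask],
            self.elements[mask],
            self.res_seq[mask],
            self.res_names[mask],
            self.chain_ids[mask],
        )

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def atom_index(self, res_seq: int, atom_name: str) -> int:
        idx = np.flatnonzero((self.res_seq == res_seq) & (self.atom_names == atom_name))
        if len(idx) == 0:
            raise KeyError(f"atom {atom_name} of residue {res_seq} not found")
        return int(idx[0])

    def residue_mask(self, res_seq: int) -> np.ndarray:
        return self.res_seq == res_seq

    def residue_ids(self) -> np.ndarray:
        """Distinct residue numbers in order of first appearance."""
        _, first = np.unique(self.res_seq, return_index=True)
        return self.res_seq[np.sort(first)]

    @staticmethod
    def concat(parts: list["Structure"]) -> "Structure":
        return Structure(
            np.concatenate([p.coords for p in parts]),
            np.concatenate([p.atom_names for p in parts]),
            np.concatenate([p.elements for p in parts]),
            np.concatenate([p.res_seq for p in parts]),
            np.concatenate([p.res_names for p in parts]),
            np.concatenate([p.chain_ids for p in parts]),
        )


def read_pdb(path, chain: str | None = None, hetero: bool = False) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model only)."""
    import biotite.structure.io.pdb as pdb

    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    mask = np.ones(arr.array_length(), dtype=bool)
    if chain is not None:
        mask &= arr.chain_id == chain
    if not hetero:
        mask &= ~arr.hetero
    arr = arr[mask]
    return Structure(
        arr.coord,
        arr.atom_name.astype(object),
        np.array([e.capitalize() for e in arr.element], dtype=object),
        arr.res_id,
        arr.res_name.astype(object),
        arr.chain_id.astype(object),
    )


def write_pdb(structure: Structure, path) -> None:
    import biotite.structure as bst
    import biotite.structure.io.pdb as pdb

    n = len(structure)
    arr = bst.AtomArray(n)
    arr.coord = structure.coords
    arr.atom_name = structure.atom_names.astype("U6")
    arr.element = np.array([e.upper() for e in structure.elements], dtype="U2")
    arr.res_id = structure.res_seq
    arr.res_name = structure.res_names.astype("U5")
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.hetero = np.zeros(n, dtype=bool)
    f = pdb.PDBFile()
    f.set_structure(arr)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    f.write(str(path))
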