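"""Ligand conformer wrapper around RDKit molecules.

Exposes the arrays the optimizer, scoring and APF code need: coordinates,
elements, Gasteiger charges, rotatable-bond torsions with their downstream
atom sets, aromatic atoms, donor/acceptor typing and protonated amine
centers.
"""

from __future__ import annotations

import numpy as np

_ROTATABLE_SMARTS = "[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]"


class LigandConformer:
    def __init__(self, mol):
        from rdkit import Chem

        if mol.GetNumConformers() == 0:
            raise ValueError("ligand has no 3D conformer")
        self.mol = mol
        self.elements = np.array([a.GetSymbol() for a in mol.GetAtoms()], dtype=object)
        self.charges = np.array(
            [float(a.GetProp("_GasteigerCharge")) if a.HasProp("_GasteigerCharge") else 0.0
             for a in mol.GetAtoms()]
        )
        self.bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
        self.aromatic_idx = np.array(
            [a.GetIdx() for a in mol.GetAtoms() if a.GetIsAromatic()], dtype=int
        )
        self.donor_h = []  # (heavy donor idx, H idx)
        for a in mol.GetAtoms():
            if a.GetSymbol() in ("N", "O"):
                for nb in a.GetNeighbors():
                    if nb.GetSymbol() == "H":
                        self.donor_h.append((a.GetIdx(), nb.GetIdx()))
        self.acceptors = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetSymbol() == "O"
            or (a.GetSymbol() == "N" and a.GetFormalCharge() <= 0 and a.GetTotalNumHs() < 3)
        ]
        self.basic_n = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetSymbol() == "N" and a.GetFormalCharge() > 0
        ]
        self.rotatable = self._find_rotatable()
        self._coords = np.array(mol.GetConformer().GetPositions(), dtype=float)

    # ------------------------------------------------------------------ basics

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    @coords.setter
    def coords(self, value):
        self._coords = np.asarray(value, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self._coords)

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def copy(self) -> "LigandConformer":
        new = LigandConformer.__new__(LigandConformer)
        new.__dict__.update(self.__dict__)
        new._coords = self._coords.copy()
        return new

    def sync_conformer(self) -> None:
        """Write current coordinates back into the RDKit conformer."""
        conf = self.mol.GetConformer()
        for i, xyz in enumerate(self._coords):
            conf.SetAtomPosition(i, [float(x) for x in xyz])

    # --------------------------------------------------------------- torsions

    def _find_rotatable(self):
        from rdkit import Chem

        patt = Chem.MolFromSmarts(_ROTATABLE_SMARTS)
        seen = set()
        out = []
        adj = {a.GetIdx(): [n.GetIdx() for n in a.GetNeighbors()] for a in self.mol.GetAtoms()}
        for j, k in self.mol.GetSubstructMatches(patt):
            key = (min(j, k), max(j, k))
            if key in seen:
                continue
            seen.add(key)
            downstream = self._downstream(j, k, adj)
            i = next(n for n in adj[j] if n != k)
            l = next(n for n in adj[k] if n != j)
            out.append({"bond": (j, k), "downstream": downstream, "quad": (i, j, k, l)})
        return out

    @staticmethod
    def _downstream(j, k, adj):
        """Atoms on the k side when bond j-k is cut (excluding k itself is
        not desired: rotation moves k's substituents, so include all atoms
        reachable from k without passing j, minus k)."""
        seen = {j, k}
        stack = [k]
        while stack:
            a = stack.pop()
            for b in adj[a]:
                if b not in seen:
                    seen.add(b)
                    stack.append(b)
        seen.discard(j)
        seen.discard(k)
        return np.array(sorted(seen), dtype=int)

    @property
    def n_rotatable(self) -> int:
        return len(self.rotatable)

    def torsion_quads(self, barrier: float = 0.3):
        return [(*r["quad"], barrier) for r in self.rotatable]

    def rotate_torsion(self, index: int, angle_deg: float) -> None:
        """Rotate the downstream atom set of rotatable bond ``index`` about
        its bond axis (in place); bond lengths/angles are untouched."""
        from .geometry import rotation_about_axis

        rot = self.rotatable[index]
        j, k = rot["bond"]
        axis = self._coords[k] - self._coords[j]
        r = rotation_about_axis(axis, angle_deg)
        pivot = self._coords[k]
        ds = rot["downstream"]
        self._coords[ds] = (self._coords[ds] - pivot) @ r.T + pivot

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        self._coords = self._coords @ rotation.T + translation

    def torsion_vector(self) -> np.ndarray:
        from .geometry import dihedral

        return np.array(
            [dihedral(*(self._coords[a] for a in r["quad"])) for r in self.rotatable]
        )


def ligand_structure_arrays(ligand: LigandConformer):
    """(names, elements, res_seq, res_names) arrays for embedding the ligand
    into a Structure/EnergySystem after the protein block."""
    n = len(ligand)
    counts: dict[str, int] = {}
    names = []
    for e in ligand.elements:
        counts[e] = counts.get(e, 0) + 1
        names.append(f"{e}{counts[e]}")
    return (
        np.array(names, dtype=object),
        ligand.elements.copy(),
        np.full(n, 9999, dtype=int),
        np.array(["LIG"] * n, dtype=object),
    )
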