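"""Surrogate force-field parameter tables.

These are generic published element parameters (Lennard-Jones wells, van der
Waals radii, Pauling electronegativities) plus simple fixed partial charges
for protein polar groups; ligand charges come from Gasteiger assignment.
The tables are deliberately small: the staging/restraint/scoring logic is
the point, not any particular energy model.
"""

from __future__ import annotations

import numpy as np

# element -> (epsilon kcal/mol, sigma Angstrom), Lorentz-Berthelot combination
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (0.016, 2.00),
    "C": (0.086, 3.40),
    "N": (0.170, 3.25),
    "O": (0.210, 2.96),
    "S": (0.250, 3.56),
    "P": (0.200, 3.74),
    "F": (0.061, 3.12),
    "Cl": (0.265, 3.47),
    "Br": (0.320, 3.62),
}

# vdW radii for surface/volume/pocket grids
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
}

PAULING_ELECTRONEGATIVITY: dict[str, float] = {
    "H": 2.20,
    "C": 2.55,
    "N": 3.04,
    "O": 3.44,
    "S": 2.58,
    "P": 2.19,
    "F": 3.98,
    "Cl": 3.16,
    "Br": 2.96,
}

# fixed partial charges for protein atoms: (res_name, atom_name) first, then
# atom-name fallback for the backbone
_BACKBONE_CHARGES = {"N": -0.35, "H": 0.25, "CA": 0.10, "C": 0.55, "O": -0.55}
_SIDECHAIN_CHARGES: dict[tuple[str, str], float] = {
    ("ASP", "CG"): 0.60,
    ("ASP", "OD1"): -0.80,
    ("ASP", "OD2"): -0.80,
    ("GLU", "CD"): 0.60,
    ("GLU", "OE1"): -0.80,
    ("GLU", "OE2"): -0.80,
    ("LYS", "NZ"): 1.00,
    ("ARG", "CZ"): 0.60,
    ("ARG", "NH1"): 0.20,
    ("ARG", "NH2"): 0.20,
    ("SER", "OG"): -0.40,
    ("SER", "HG"): 0.40,
    ("THR", "OG1"): -0.40,
    ("THR", "HG1"): 0.40,
    ("TYR", "OH"): -0.40,
    ("TYR", "HH"): 0.40,
}

# heavy ring atoms of aromatic side chains (for aromatic-contact terms)
AROMATIC_RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

# standard exposed side-chain polar-group areas in a Gly-X-Gly tripeptide
# (theoretical max ASA scale, A^2); used as the reference for the 25 %
# exposure rule
GLY_X_GLY_POLAR_AREA: dict[str, float] = {
    "SER": 80.0,
    "THR": 90.0,
    "ASN": 110.0,
    "GLN": 130.0,
    "ASP": 105.0,
    "GLU": 130.0,
    "LYS": 165.0,
    "ARG": 200.0,
    "HIS": 130.0,
    "TYR": 110.0,
    "TRP": 95.0,
}

POLAR_RESIDUES = tuple(GLY_X_GLY_POLAR_AREA)

# side-chain atoms counted as the charged/polar group of each residue type
POLAR_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
    "ASP": ("OD1", "OD2", "CG"),
    "GLU": ("OE1", "OE2", "CD"),
    "LYS": ("NZ", "CE"),
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "TYR": ("OH",),
    "TRP": ("NE1",),
}


def lj_arrays(elements) -> tuple[np.ndarray, np.ndarray]:
    eps = np.array([LJ_PARAMS.get(e, LJ_PARAMS["C"])[0] for e in elements])
    sig = np.array([LJ_PARAMS.get(e, LJ_PARAMS["C"])[1] for e in elements])
    return eps, sig


def vdw_radius_array(elements) -> np.ndarray:
    return np.array([VDW_RADII.get(e, 1.7) for e in elements])


def protein_charges(res_names, atom_names) -> np.ndarray:
    q = np.zeros(len(atom_names))
    for i, (rn, an) in enumerate(zip(res_names, atom_names)):
        if (rn, an) in _SIDECHAIN_CHARGES:
            q[i] = _SIDECHAIN_CHARGES[(rn, an)]
        elif an in _BACKBONE_CHARGES:
            q[i] = _BACKBONE_CHARGES[an]
    return q
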