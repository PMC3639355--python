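"""Surrogate energy model: soft-core Lennard-Jones, distance-dependent
dielectric electrostatics, a geometric hydrogen-bond well, harmonic tethers
and flat-bottom anchor restraints.

The soft-core form is ``E_soft = E / (1 + lam * E / cap)`` applied to the
repulsive (E > 0) branch only, so at full softness (lam = 1) no atom pair
can contribute more than ``cap`` kcal/mol, and lam -> 0 recovers the plain
6-12 potential monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import forcefield as ff

COULOMB_K = 332.06  # kcal A / (mol e^2)


@dataclass
class EnergyParams:
    softness: float = 0.0  # lam in [0, 1]; 1 = fully soft
    vdw_cap: float = 2.0  # kcal/mol, per-pair cap at lam = 1
    dielectric_model: str = "distance_dependent"  # or "constant"
    dielectric_eps: float = 4.0
    hbond_depth: float = 2.0  # kcal/mol well depth
    hbond_r_full: tuple[float, float] = (1.6, 2.5)  # H...A, full strength
    hbond_r_zero: float = 3.2  # H...A where the bond fades to zero

    def validate(self) -> None:
        if not (0.0 <= self.softness <= 1.0):
            raise ValueError(f"softness must be in [0,1], got {self.softness}")
        if self.vdw_cap <= 0:
            raise ValueError("vdw_cap must be positive")


@dataclass
class Tether:
    """Harmonic restraint of one atom to a fixed reference point (target 0 A)."""

    atom_index: int
    reference: np.ndarray
    k: float = 1.0  # kcal/mol/A^2


@dataclass
class AnchorRestraint:
    """Flat-bottom quadratic restraint between two atom-set centroids."""

    atoms_a: tuple[int, ...]
    atoms_b: tuple[int, ...]
    target: float
    half_width: float
    k: float = 1.0

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("anchor half-width must be > 0")


@dataclass
class RestraintSet:
    tethers: list[Tether] = field(default_factory=list)
    anchors: list[AnchorRestraint] = field(default_factory=list)


class EnergySystem:
    """Atom arrays + nonbonded exclusions for one receptor/ligand system.

    Protein bonds are detected by distance, ligand bonds come from the
    supplied bond list; 1-2, 1-3 and 1-4 pairs are excluded from the
    nonbonded sums.
    """

    def __init__(self, coords, elements, charges, bonds):
        # own copy: callers' structures must never be mutated through us
        self.coords = np.array(coords, dtype=float).reshape(-1, 3)
        self.elements = np.asarray(elements, dtype=object)
        self.charges = np.asarray(charges, dtype=float)
        n = len(self.coords)
        self.eps, self.sigma = ff.lj_arrays(self.elements)
        adj = np.zeros((n, n), dtype=bool)
        for i, j in bonds:
            adj[i, j] = adj[j, i] = True
        self.adjacency = adj
        a = adj.astype(np.int16)
        a2 = (a @ a) > 0
        a3 = (a2.astype(np.int16) @ a) > 0
        excl = adj | a2 | a3
        np.fill_diagonal(excl, True)
        self.exclusion = excl

    def __len__(self) -> int:
        return len(self.coords)


def detect_bonds(coords, elements) -> list[tuple[int, int]]:
    """Distance-based covalent bond detection (heavy-heavy < 1.9 A,
    hydrogen-heavy < 1.3 A)."""
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    elements = np.asarray(elements, dtype=object)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(1.9, output_type="ndarray")
    bonds = []
    for i, j in pairs:
        d = np.linalg.norm(coords[i] - coords[j])
        hy = (elements[i] == "H") or (elements[j] == "H")
        if elements[i] == "H" and elements[j] == "H":
            continue
        if (hy and d < 1.3) or (not hy and d < 1.9):
            bonds.append((int(i), int(j)))
    return bonds


def system_from_structure(structure, extra_charges=None) -> EnergySystem:
    charges = ff.protein_charges(structure.res_names, structure.atom_names)
    if extra_charges is not None:
        charges = charges + extra_charges
    bonds = detect_bonds(structure.coords, structure.elements)
    return EnergySystem(structure.coords, structure.elements, charges, bonds)


# ------------------------------------------------------------------ nonbonded


def _lj_pair_energy(r2, eps_ij, sig_ij, softness, cap):
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = (sig_ij**2 / r2) ** 3
        e = 4.0 * eps_ij * (sr6 * sr6 - sr6)
    e = np.where(np.isnan(e), np.inf, e)
    if softness > 0:
        rep = e > 0
        e = np.where(rep, e / (1.0 + softness * e / cap), e)
    return e


def vdw_energy(system: EnergySystem, params: EnergyParams) -> float:
    """Total soft-core Lennard-Jones energy over all non-excluded pairs."""
    params.validate()
    iu, ju = np.triu_indices(len(system), k=1)
    keep = ~system.exclusion[iu, ju]
    iu, ju = iu[keep], ju[keep]
    r2 = np.sum((system.coords[iu] - system.coords[ju]) ** 2, axis=1)
    eps_ij = np.sqrt(system.eps[iu] * system.eps[ju])
    sig_ij = 0.5 * (system.sigma[iu] + system.sigma[ju])
    return float(np.sum(_lj_pair_energy(r2, eps_ij, sig_ij, params.softness, params.vdw_cap)))


def electrostatic_energy(system: EnergySystem, params: EnergyParams) -> float:
    """Coulomb sum; with the distance-dependent model eps(r) = eps * r."""
    iu, ju = np.triu_indices(len(system), k=1)
    keep = ~system.exclusion[iu, ju]
    iu, ju = iu[keep], ju[keep]
    qq = system.charges[iu] * system.charges[ju]
    nz = qq != 0.0
    iu, ju, qq = iu[nz], ju[nz], qq[nz]
    r = np.linalg.norm(system.coords[iu] - system.coords[ju], axis=1)
    if params.dielectric_model == "distance_dependent":
        return float(np.sum(COULOMB_K * qq / (params.dielectric_eps * r * r)))
    return float(np.sum(COULOMB_K * qq / (params.dielectric_eps * r)))


def group_nonbonded_energy(
    system: EnergySystem, params: EnergyParams, group: np.ndarray
) -> float:
    """vdW + electrostatic energy between ``group`` atoms and all others.

    This is the exact move-delta kernel: a rigid or torsional move of
    ``group`` changes only these cross terms.
    """
    group = np.asarray(group, dtype=int)
    rest = np.setdiff1d(np.arange(len(system)), group, assume_unique=False)
    if len(group) == 0 or len(rest) == 0:
        return 0.0
    d = cdist(system.coords[group], system.coords[rest])
    mask = ~system.exclusion[np.ix_(group, rest)]
    r2 = d**2
    eps_ij = np.sqrt(np.outer(system.eps[group], system.eps[rest]))
    sig_ij = 0.5 * (system.sigma[group][:, None] + system.sigma[rest][None, :])
    e_vdw = _lj_pair_energy(r2, eps_ij, sig_ij, params.softness, params.vdw_cap)
    qq = np.outer(system.charges[group], system.charges[rest])
    if params.dielectric_model == "distance_dependent":
        e_el = COULOMB_K * qq / (params.dielectric_eps * r2)
    else:
        e_el = COULOMB_K * qq / (params.dielectric_eps * d)
    return float(np.sum((e_vdw + e_el)[mask]))


# ------------------------------------------------------------------- hbond


def hbond_energy(donor, hydrogen, acceptor, params: EnergyParams) -> float:
    """Energy of one D-H...A hydrogen bond (<= 0).

    Well depth scaled by a distance switch on H...A (full inside
    ``hbond_r_full``, fading to 0 at ``hbond_r_zero``) and an angular factor
    cos^2(D-H...A) applied for angles > 90 deg (0 otherwise).
    """
    donor = np.asarray(donor, float)
    hydrogen = np.asarray(hydrogen, float)
    acceptor = np.asarray(acceptor, float)
    r = float(np.linalg.norm(acceptor - hydrogen))
    lo, hi = params.hbond_r_full
    if r <= hi:
        s = 1.0
    elif r < params.hbond_r_zero:
        s = (params.hbond_r_zero - r) / (params.hbond_r_zero - hi)
    else:
        return 0.0
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if ang <= 90.0:
        return 0.0
    return float(-params.hbond_depth * s * cosang**2)


def hbond_sum(
    system: EnergySystem,
    donor_h: list[tuple[int, int]],
    acceptors: list[int],
    params: EnergyParams,
) -> float:
    """Sum of hydrogen-bond energies over (donor, H) pairs vs acceptor atoms."""
    total = 0.0
    for d, h in donor_h:
        for a in acceptors:
            if a == d or a == h:
                continue
            total += hbond_energy(system.coords[d], system.coords[h], system.coords[a], params)
    return total


# ----------------------------------------------------------------- restraints


def tether_energy(system: EnergySystem, restraints: RestraintSet, strength_scale: float = 1.0) -> float:
    """Sum of k * scale * d^2 over all tethers; scale 0 switches them off."""
    if strength_scale == 0.0 or not restraints.tethers:
        return 0.0
    e = 0.0
    for t in restraints.tethers:
        d2 = float(np.sum((system.coords[t.atom_index] - t.reference) ** 2))
        e += t.k * strength_scale * d2
    return e


def anchor_restraint_energy(system: EnergySystem, restraints: RestraintSet) -> float:
    """Flat-bottom quadratic anchors: 0 inside [target +- w], k*(excess)^2
    outside (C1-continuous at the boundaries)."""
    e = 0.0
    for a in restraints.anchors:
        ca = system.coords[list(a.atoms_a)].mean(axis=0)
        cb = system.coords[list(a.atoms_b)].mean(axis=0)
        d = float(np.linalg.norm(ca - cb))
        excess = abs(d - a.target) - a.half_width
        if excess > 0:
            e += a.k * excess * excess
    return e


def flat_bottom(d: float, target: float, half_width: float, k: float = 1.0) -> float:
    """Scalar flat-bottom quadratic (exposed for direct scoring use)."""
    excess = abs(d - target) - half_width
    return k * excess * excess if excess > 0 else 0.0


# -------------------------------------------------------------------- total


def torsion_strain(coords, torsions) -> float:
    """Simple 3-fold rotational strain over (i, j, k, l, barrier) entries."""
    from .geometry import dihedral

    e = 0.0
    for i, j, k, l, v in torsions:
        phi = np.deg2rad(dihedral(coords[i], coords[j], coords[k], coords[l]))
        e += 0.5 * v * (1.0 + np.cos(3.0 * phi))
    return float(e)


def total_energy(
    system: EnergySystem,
    params: EnergyParams,
    restraints: RestraintSet | None = None,
    tether_scale: float = 1.0,
    hbond_pairs: tuple[list[tuple[int, int]], list[int]] | None = None,
    torsions: list | None = None,
    term_scales: dict[str, float] | None = None,
) -> tuple[float, dict[str, float]]:
    """Total energy with a per-term breakdown.

    ``term_scales`` multiplies individual terms (0 disables a term without
    computing it); a non-finite term raises, naming the term.
    """
    scales = {"vdw": 1.0, "elec": 1.0, "hbond": 1.0, "torsion": 1.0, "tether": 1.0, "anchor": 1.0}
    if term_scales:
        scales.update(term_scales)
    restraints = restraints or RestraintSet()
    breakdown: dict[str, float] = {}
    breakdown["vdw"] = scales["vdw"] * vdw_energy(system, params) if scales["vdw"] else 0.0
    breakdown["elec"] = (
        scales["elec"] * electrostatic_energy(system, params) if scales["elec"] else 0.0
    )
    if scales["hbond"] and hbond_pairs is not None:
        breakdown["hbond"] = scales["hbond"] * hbond_sum(system, hbond_pairs[0], hbond_pairs[1], params)
    else:
        breakdown["hbond"] = 0.0
    if scales["torsion"] and torsions:
        breakdown["torsion"] = scales["torsion"] * torsion_strain(system.coords, torsions)
    else:
        breakdown["torsion"] = 0.0
    breakdown["tether"] = (
        scales["tether"] * tether_energy(system, restraints, tether_scale) if scales["tether"] else 0.0
    )
    breakdown["anchor"] = (
        scales["anchor"] * anchor_restraint_energy(system, restraints) if scales["anchor"] else 0.0
    )
    for name, value in breakdown.items():
        if not np.isfinite(value):
            raise ValueError(f"non-finite energy term: {name} = {value}")
    return float(sum(breakdown.values())), breakdown
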