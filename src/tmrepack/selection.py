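"""Receptor-model selection: grid-map ligand docking, pose acceptance by
key-interaction criteria, model ranking by unique accepted agonists, RMSD
analytics, binding-site box transfer and atom-property-field summaries.

The docking engine is intentionally minimal: four interaction classes (van
der Waals, electrostatic, hydrogen bonding, hydrophobic) are precomputed as
grid maps over the binding-site box and a torsion/rigid-body Monte Carlo is
run against them.  Its job is to exercise the selection logic end-to-end,
not to compete with production docking codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import forcefield as ff
from .bundle import BundleState
from .energy import EnergyParams, hbond_energy
from .geometry import kabsch, rotation_about_axis
from .ligands import LigandConformer
from .structure import Structure


# ------------------------------------------------------------------ grid maps


@dataclass
class GridMaps:
    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    maps: dict  # name -> 3D array

    def _interp(self, name: str, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation with clamping to the box interior."""
        g = (points - self.origin) / self.spacing
        hi = np.array(self.shape) - 1.000001
        outside = np.clip(g, 0, None) - np.clip(g, None, hi)
        excursion = np.linalg.norm(np.maximum(g * 0, np.abs(outside)), axis=1)
        g = np.clip(g, 0.0, hi)
        i0 = np.floor(g).astype(int)
        f = g - i0
        m = self.maps[name]
        out = np.zeros(len(points))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (f[:, 0] if dx else 1 - f[:, 0])
                        * (f[:, 1] if dy else 1 - f[:, 1])
                        * (f[:, 2] if dz else 1 - f[:, 2])
                    )
                    out += w * m[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        # walking out of the box is heavily penalized
        return out + 10.0 * excursion * self.spacing

    def ligand_energy(self, ligand: LigandConformer, coords: np.ndarray | None = None) -> float:
        c = ligand.coords if coords is None else coords
        eps, sig = ff.lj_arrays(ligand.elements)
        a_coef = np.sqrt(eps) * sig**6
        b_coef = np.sqrt(eps) * sig**3
        e = float(np.sum(a_coef * self._interp("vdw_rep", c)))
        e -= float(np.sum(b_coef * self._interp("vdw_att", c)))
        e += float(np.sum(ligand.charges * self._interp("elec", c)))
        if len(ligand.acceptors):
            e += float(np.sum(self._interp("hb_acc", c[ligand.acceptors])))
        h_idx = [h for _, h in ligand.donor_h]
        if h_idx:
            e += float(np.sum(self._interp("hb_don", c[h_idx])))
        carbons = np.flatnonzero(ligand.elements == "C")
        if len(carbons):
            e += float(np.sum(self._interp("hydrophobic", c[carbons])))
        return e


def compute_grid_maps(
    structure: Structure,
    box_center: np.ndarray,
    box_size: float = 10.0,
    spacing: float = 0.5,
    margin: float = 4.0,
    params: EnergyParams | None = None,
) -> GridMaps:
    """Precompute the four interaction-class maps over a cubic box."""
    params = params or EnergyParams()
    half = box_size / 2.0 + margin
    origin = np.asarray(box_center, dtype=float) - half
    n = int(round(2 * half / spacing)) + 1
    axes = [origin[d] + spacing * np.arange(n) for d in range(3)]
    shape = (n, n, n)

    coords = structure.coords
    elements = structure.elements
    eps, sig = ff.lj_arrays(elements)
    charges = ff.protein_charges(structure.res_names, structure.atom_names)
    # protein polar hydrogens / acceptor oxygens for the hbond maps
    acc_idx = np.flatnonzero(elements == "O")
    don_h = []
    tree_all = cKDTree(coords)
    for i in np.flatnonzero(elements == "H"):
        nb = tree_all.query_ball_point(coords[i], 1.3)
        if any(elements[j] in ("N", "O") for j in nb if j != i):
            don_h.append(i)
    don_h = np.array(don_h, dtype=int)

    maps = {k: np.zeros(shape) for k in ("vdw_rep", "vdw_att", "elec", "hb_acc", "hb_don", "hydrophobic")}
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts_slice = np.stack([gx, gy, gz], axis=-1)
    cutoff = 8.0
    for iz in range(n):  # chunk over z-planes to bound memory
        pts = pts_slice[:, :, iz, :].reshape(-1, 3)
        neighbor_lists = tree_all.query_ball_point(pts, cutoff)
        flat_rep = np.zeros(len(pts))
        flat_att = np.zeros(len(pts))
        flat_elec = np.zeros(len(pts))
        flat_acc = np.zeros(len(pts))
        flat_don = np.zeros(len(pts))
        flat_hyd = np.zeros(len(pts))
        for p, nb in enumerate(neighbor_lists):
            if not nb:
                continue
            nb = np.asarray(nb)
            r = np.linalg.norm(coords[nb] - pts[p], axis=1)
            r = np.maximum(r, 0.9)
            flat_rep[p] = np.sum(4.0 * np.sqrt(eps[nb]) * sig[nb] ** 6 / r**12)
            flat_att[p] = np.sum(4.0 * np.sqrt(eps[nb]) * sig[nb] ** 3 / r**6)
            q = charges[nb]
            flat_elec[p] = np.sum(332.06 * q / (params.dielectric_eps * r * r))
            hy = nb[elements[nb] == "C"]
            if len(hy):
                rh = np.linalg.norm(coords[hy] - pts[p], axis=1)
                flat_hyd[p] = np.sum(-0.02 * np.clip(1.0 - rh / 6.0, 0.0, 1.0))
            # distance-only hbond wells (angles handled in rescoring)
            dh = np.intersect1d(nb, don_h)
            if len(dh):
                rd = np.linalg.norm(coords[dh] - pts[p], axis=1)
                flat_acc[p] = -params.hbond_depth * np.max(_hb_switch(rd, params))
            ac = np.intersect1d(nb, acc_idx)
            if len(ac):
                ra = np.linalg.norm(coords[ac] - pts[p], axis=1)
                flat_don[p] = -params.hbond_depth * np.max(_hb_switch(ra, params))
        maps["vdw_rep"][:, :, iz] = np.minimum(flat_rep, 1e4).reshape(n, n)
        maps["vdw_att"][:, :, iz] = flat_att.reshape(n, n)
        maps["elec"][:, :, iz] = np.clip(flat_elec, -50, 50).reshape(n, n)
        maps["hb_acc"][:, :, iz] = flat_acc.reshape(n, n)
        maps["hb_don"][:, :, iz] = flat_don.reshape(n, n)
        maps["hydrophobic"][:, :, iz] = flat_hyd.reshape(n, n)
    return GridMaps(origin=origin, spacing=spacing, shape=shape, maps=maps)


def _hb_switch(r, params):
    lo, hi = params.hbond_r_full
    s = np.where(r <= hi, 1.0, np.clip((params.hbond_r_zero - r) / (params.hbond_r_zero - hi), 0.0, 1.0))
    return s


# -------------------------------------------------------------------- docking


@dataclass
class PoseRecord:
    compound_id: str
    coords: np.ndarray
    energy: float
    hbond_to_asp: float = 0.0
    hbond_to_ser: float = 0.0
    aromatic_vdw: float = 0.0
    accepted: bool = False
    reasons: list = field(default_factory=list)
    pose_index: int = -1


def dock_ligand(
    maps: GridMaps,
    ligand: LigandConformer,
    seed: int = 0,
    n_poses: int = 30,
    n_runs: int = 20,
    n_steps: int = 300,
    compound_id: str = "ligand",
    t_start: float = 600.0,
    t_end: float = 100.0,
) -> list[PoseRecord]:
    """Monte Carlo docking of one compound against precomputed grid maps.

    Each run randomizes torsions and rigid placement inside the box, anneals
    with Metropolis acceptance, and keeps its best pose; the pooled poses
    are deduplicated at 1 A heavy-atom RMSD and the ``n_poses`` lowest-energy
    distinct conformations are returned (empty, with a warning, if the
    ligand never fits the box).
    """
    rng = np.random.default_rng(seed)
    center = maps.origin + maps.spacing * (np.array(maps.shape) - 1) / 2.0
    half = maps.spacing * (maps.shape[0] - 1) / 2.0
    collected: list[tuple[float, np.ndarray]] = []

    for _ in range(n_runs):
        pose = ligand.copy()
        for t in range(pose.n_rotatable):
            pose.rotate_torsion(t, rng.uniform(-180, 180))
        axis = rng.normal(size=3)
        pose.transform(rotation_about_axis(axis, rng.uniform(0, 360)), np.zeros(3))
        pose.coords = pose.coords - pose.coords[pose.heavy_mask].mean(axis=0)
        start = center + rng.uniform(-half / 3, half / 3, 3)
        pose.coords = pose.coords + start
        e = maps.ligand_energy(pose)
        best_e, best_c = e, pose.coords.copy()
        for step in range(n_steps):
            frac = step / max(1, n_steps - 1)
            temp = t_start * (t_end / t_start) ** frac
            old = pose.coords.copy()
            kind = rng.integers(3)
            if kind == 0:
                pose.coords = pose.coords + rng.normal(0, 0.4, 3)
            elif kind == 1:
                c = pose.coords[pose.heavy_mask].mean(axis=0)
                r = rotation_about_axis(rng.normal(size=3), rng.normal(0, 10.0))
                pose.coords = (pose.coords - c) @ r.T + c
            elif pose.n_rotatable:
                pose.rotate_torsion(int(rng.integers(pose.n_rotatable)), rng.normal(0, 20.0))
            e_new = maps.ligand_energy(pose)
            if e_new - e <= 0 or rng.random() < np.exp(-(e_new - e) / (0.0019872 * temp)):
                e = e_new
                if e < best_e:
                    best_e, best_c = e, pose.coords.copy()
            else:
                pose.coords = old
        collected.append((best_e, best_c))

    collected.sort(key=lambda t: t[0])
    heavy = ligand.heavy_mask
    unique: list[tuple[float, np.ndarray]] = []
    for e, c in collected:
        if all(np.sqrt(np.mean(np.sum((c[heavy] - uc[heavy]) ** 2, axis=1))) > 1.0 for _, uc in unique):
            unique.append((e, c))
        if len(unique) >= n_poses:
            break
    if not unique:
        import warnings

        warnings.warn(f"{compound_id}: no pose could be generated in the box")
    return [
        PoseRecord(compound_id=compound_id, coords=c, energy=float(e), pose_index=i)
        for i, (e, c) in enumerate(unique)
    ]


# --------------------------------------------------------------- pose filters


def evaluate_pose(
    pose: PoseRecord,
    bundle: BundleState,
    ligand: LigandConformer,
    target_spec,
    criteria=None,
    params: EnergyParams | None = None,
) -> PoseRecord:
    """Compute the three key-interaction energies and the accept verdict.

    Accepted iff the amine-to-aspartate hydrogen bond, the best serine
    hydrogen bond and the aromatic-aromatic vdW energy are all at or below
    their ceilings.  All poses of a stack are evaluated; there is no energy
    pre-threshold.
    """
    from .scoring import aromatic_vdw_energy, serine_hbond_energy

    params = params or EnergyParams()
    criteria = criteria or target_spec.acceptance
    st = bundle.structure
    lig = ligand.copy()
    lig.coords = pose.coords

    od = np.flatnonzero(
        (st.res_seq == target_spec.aspartate_residue) & np.isin(st.atom_names, ("OD1", "OD2"))
    )
    if len(od) == 0:
        raise KeyError(f"aspartate residue {target_spec.aspartate_residue} not in model")
    e_asp = 0.0
    for d, h in lig.donor_h:
        if d not in lig.basic_n:
            continue
        for a in od:
            e_asp += hbond_energy(lig.coords[d], lig.coords[h], st.coords[a], params)
    e_ser = serine_hbond_energy(bundle, lig, target_spec.serine_residues, params)
    e_arom = aromatic_vdw_energy(bundle, lig, target_spec.aromatic_residues, params)

    reasons = []
    if e_asp > criteria.hbond_asp_max:
        reasons.append("aspartate hydrogen bond")
    if e_ser > criteria.hbond_ser_max:
        reasons.append("serine hydrogen bond")
    if len(lig.aromatic_idx) == 0:
        reasons.append("aromatic vdW (ligand has no aromatic atoms)")
    elif e_arom > criteria.aromatic_vdw_max:
        reasons.append("aromatic vdW")
    pose.hbond_to_asp = float(e_asp)
    pose.hbond_to_ser = float(e_ser)
    pose.aromatic_vdw = float(e_arom)
    pose.accepted = len(reasons) == 0
    pose.reasons = reasons
    return pose


def best_accepted_pose(stack: list[PoseRecord]) -> PoseRecord | None:
    """Lowest docking energy among accepted poses (ties: lower pose index)."""
    accepted = [p for p in stack if p.accepted]
    if not accepted:
        return None
    return min(accepted, key=lambda p: (p.energy, p.pose_index))


@dataclass
class Compound:
    compound_id: str
    is_agonist: bool
    enantiomer_group: str | None = None

    @property
    def group(self) -> str:
        return self.enantiomer_group or self.compound_id


def rank_models(
    accept_table: dict, compounds: list[Compound], model_scores: dict | None = None
):
    """Rank receptor models by the number of unique agonists accepted.

    ``accept_table[model_id][compound_id]`` is truthy when at least one pose
    of that compound was accepted for that model; enantiomer pairs count
    once.  Ties break by (ascending) model total score, then model id.
    Returns a list of (model_id, n_unique_agonists) best-first.
    """
    model_scores = model_scores or {}
    by_group: dict[str, list[Compound]] = {}
    for c in compounds:
        if c.is_agonist:
            by_group.setdefault(c.group, []).append(c)
    rows = []
    for model_id in sorted(accept_table):
        accepted = accept_table[model_id]
        n = sum(
            1
            for group, members in by_group.items()
            if any(accepted.get(m.compound_id) for m in members)
        )
        rows.append((model_id, n))
    rows.sort(key=lambda r: (-r[1], model_scores.get(r[0], 0.0), r[0]))
    return rows


# ------------------------------------------------------------ RMSD utilities


def _match_atoms(reference: Structure, model: Structure, selection) -> tuple[np.ndarray, np.ndarray]:
    """Pair up atoms by (residue number, atom name) keys under a selection.

    ``selection``: "ca", "heavy", or an explicit list of (res_seq, atom_name).
    """
    def keys(st, mask):
        return [(int(r), str(a)) for r, a in zip(st.res_seq[mask], st.atom_names[mask])]

    if selection == "ca":
        mref = reference.atom_names == "CA"
        mmod = model.atom_names == "CA"
    elif selection == "heavy":
        mref = reference.heavy_mask
        mmod = model.heavy_mask
    else:
        wanted = set((int(r), str(a)) for r, a in selection)
        mref = np.array([k in wanted for k in keys(reference, np.ones(len(reference), bool))])
        mmod = np.array([k in wanted for k in keys(model, np.ones(len(model), bool))])
    kref = keys(reference, mref)
    kmod = keys(model, mmod)
    common = [k for k in kref if k in set(kmod)]
    missing = sorted(set(kref) ^ set(kmod))
    if not common:
        raise ValueError(f"no common atoms under selection; unmatched: {missing[:10]}")
    if missing and selection not in ("ca", "heavy"):
        raise ValueError(f"atom-count mismatch; unmatched atoms: {missing[:20]}")
    iref = {k: i for i, k in zip(np.flatnonzero(mref), kref)}
    imod = {k: i for i, k in zip(np.flatnonzero(mmod), kmod)}
    idx_r = np.array([iref[k] for k in common])
    idx_m = np.array([imod[k] for k in common])
    return idx_r, idx_m


def superpose_and_rmsd(
    reference: Structure,
    model: Structure,
    fit="ca",
    report=None,
) -> float:
    """Least-squares superposition on the ``fit`` selection, RMSD reported on
    the ``report`` selection (defaults to the fit selection).

    The fit and report sets may differ — e.g. fit the binding-site residues
    and report the ligand RMSD.
    """
    ir_fit, im_fit = _match_atoms(reference, model, fit)
    r, t = kabsch(model.coords[im_fit], reference.coords[ir_fit])
    if report is None:
        ir_rep, im_rep = ir_fit, im_fit
    else:
        ir_rep, im_rep = _match_atoms(reference, model, report)
    moved = model.coords[im_rep] @ r.T + t
    return float(np.sqrt(np.mean(np.sum((moved - reference.coords[ir_rep]) ** 2, axis=1))))


def binding_site_residues(structure: Structure, ligand_coords, cutoff: float = 5.0) -> list[int]:
    """Residues with any heavy atom within ``cutoff`` of a ligand heavy atom."""
    heavy = structure.heavy_mask
    tree = cKDTree(np.asarray(ligand_coords, dtype=float))
    d = tree.query(structure.coords[heavy], k=1)[0]
    return sorted(set(int(r) for r in structure.res_seq[heavy][d <= cutoff]))


def binding_site_box_transfer(
    reference: Structure,
    box_center: np.ndarray,
    models: list[Structure],
    core_residues: list[int] | None = None,
    box_size: float = 10.0,
) -> list[np.ndarray]:
    """Transfer a binding-site box defined on one model to other models.

    Each model is superposed on the reference via the sequence-conserved
    core CA atoms (so one deviant helix cannot skew the alignment), then the
    atoms falling inside the box (reference coordinates) are selected.
    Returns one atom-index array per model.
    """
    box_center = np.asarray(box_center, dtype=float)
    half = box_size / 2.0
    out = []
    for model in models:
        if core_residues is None:
            sel = "ca"
        else:
            sel = [(r, "CA") for r in core_residues]
        ir, im = _match_atoms(reference, model, sel)
        r, t = kabsch(model.coords[im], reference.coords[ir])
        moved = model.coords @ r.T + t
        inside = np.all(np.abs(moved - box_center) <= half, axis=1)
        if not inside.any():
            import warnings

            warnings.warn("binding-site box is empty for one model")
        out.append(np.flatnonzero(inside))
    return out


# ------------------------------------------------------------------ APF grids


APF_CHANNELS = (
    "hydrophobicity",
    "hb_acceptor",
    "hb_donor",
    "charge",
    "sp2",
    "size",
    "electronegativity",
)


@dataclass
class APFGrid:
    channels: dict  # name -> 3D array
    origin: np.ndarray
    spacing: float

    def peak_position(self, channel: str) -> np.ndarray:
        m = self.channels[channel]
        idx = np.unravel_index(np.argmax(m), m.shape)
        return self.origin + self.spacing * np.array(idx)


def atom_properties(ligand: LigandConformer) -> dict:
    """Per-atom values of the seven properties from simple typing rules."""
    from rdkit.Chem import HybridizationType

    mol = ligand.mol
    n = len(ligand)
    props = {k: np.zeros(n) for k in APF_CHANNELS}
    h_of_donor = set(h for _, h in ligand.donor_h)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        if sym == "C" and all(nb.GetSymbol() in ("C", "H") for nb in atom.GetNeighbors()):
            props["hydrophobicity"][i] = 1.0
        if sym in ("F", "Cl", "Br", "I", "S"):
            props["hydrophobicity"][i] = 1.0
        if i in ligand.acceptors:
            props["hb_acceptor"][i] = 1.0
        if i in h_of_donor:
            props["hb_donor"][i] = 1.0
        props["charge"][i] = ligand.charges[i]
        if atom.GetHybridization() == HybridizationType.SP2 or atom.GetIsAromatic():
            props["sp2"][i] = 1.0
        props["size"][i] = ff.VDW_RADII.get(sym, 1.7)
        props["electronegativity"][i] = ff.PAULING_ELECTRONEGATIVITY.get(sym, 2.5)
    return props


def apf_grid(
    ligand: LigandConformer,
    pose_coords: list[np.ndarray],
    spacing: float = 0.5,
    half_width: float = 1.0,
) -> APFGrid:
    """Average atom property fields over an ensemble of accepted poses.

    Each atom's property value is splatted with a Gaussian kernel
    (half-width at half-maximum ``half_width``); channels are summed per
    pose and averaged over the ensemble.
    """
    if not pose_coords:
        raise ValueError("empty pose ensemble")
    sigma = half_width / np.sqrt(2.0 * np.log(2.0))
    allc = np.vstack(pose_coords)
    pad = 3.0 * sigma
    lo = allc.min(axis=0) - pad
    hi = allc.max(axis=0) + pad
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    shape = tuple(len(a) for a in axes)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    props = atom_properties(ligand)
    channels = {k: np.zeros(shape) for k in APF_CHANNELS}
    for coords in pose_coords:
        for k, vals in props.items():
            nz = np.flatnonzero(vals != 0)
            for i in nz:
                d2 = (gx - coords[i, 0]) ** 2 + (gy - coords[i, 1]) ** 2 + (gz - coords[i, 2]) ** 2
                channels[k] += vals[i] * np.exp(-d2 / (2.0 * sigma**2))
    for k in channels:
        channels[k] /= len(pose_coords)
    return APFGrid(channels=channels, origin=lo, spacing=spacing)


def write_dx(grid: APFGrid, channel: str, path) -> None:
    """Write one APF channel as an OpenDX scalar field."""
    m = grid.channels[channel]
    nx, ny, nz = m.shape
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.4f} {:.4f} {:.4f}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing:.4f} 0 0\n")
        fh.write(f"delta 0 {grid.spacing:.4f} 0\n")
        fh.write(f"delta 0 0 {grid.spacing:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {m.size} data follows\n"
        )
        flat = m.ravel()
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
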