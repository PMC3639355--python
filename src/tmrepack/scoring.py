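"""Packing, orientation and ligand scores for helix-bundle complex models.

Packing terms: solvent-excluded volume, solvent-accessible area, buried
pocket count/volume and the sum of helix-center-to-bundle-center distances.
Orientation terms: hydrophilic exposure of the membrane-embedded mid-third,
per-segment tilt beyond 50 degrees, helix-center elevation, loop-span
feasibility (3.2 A per loop residue) and the ligand anchor-residue distance.
The ligand score is target-specific (serine hydrogen bonds, aspartate
electrostatics + hydrogen bonds, restraint energies, aromatic vdW contacts).
All penalties are >= 0 and vanish on the ideal fixture bundle; lower total
scores are better throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import forcefield as ff
from .bundle import BundleState, helix_axis_segments, helix_elevations, membrane_frame
from .energy import EnergyParams, flat_bottom, hbond_energy
from .structure import Structure


# ------------------------------------------------------------------- weights


@dataclass
class ScoreWeights:
    """Per-term and top-level score weights.

    Defaults are unit weights; they are surrogate-referenced (fitted by eye
    on the synthetic decoy suite, not taken from any publication) and fully
    config-overridable.
    """

    packing_terms: dict = field(
        default_factory=lambda: {
            "volume": 0.01,
            "area": 0.01,
            "buried_pocket_count": 5.0,
            "buried_pocket_volume": 0.02,
            "helix_center_distance": 5.0,
        }
    )
    orientation_terms: dict = field(
        default_factory=lambda: {
            "hydrophilic_exposure_major": 0.05,
            "hydrophilic_exposure_all": 0.02,
            "tilt_penalty": 1.0,
            "elevation_penalty": 5.0,
            "loop_span_penalty": 1.0,
            "anchor_penalty": 1.0,
        }
    )
    ligand_terms: dict = field(
        default_factory=lambda: {
            "serine_hbond": 1.0,
            "aspartate_elec_hbond": 1.0,
            "restraints": 1.0,
            "aromatic_vdw": 1.0,
        }
    )
    top_level: dict = field(
        default_factory=lambda: {"packing": 1.0, "orientation": 1.0, "ligand": 1.0}
    )


@dataclass
class ScoreReport:
    packing: dict = field(default_factory=dict)
    orientation: dict = field(default_factory=dict)
    ligand: dict = field(default_factory=dict)
    packing_score: float = 0.0
    orientation_score: float = 0.0
    ligand_score: float = 0.0
    total_score: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


# ------------------------------------------------------- volume/area/pockets


def _sasa(structure: Structure, probe: float = 1.4, n_points: int = 256) -> np.ndarray:
    """Per-atom solvent-accessible area (Shrake-Rupley, golden-spiral points)."""
    coords = structure.coords
    radii = ff.vdw_radius_array(structure.elements) + probe
    n = len(coords)
    k = np.arange(n_points)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    zs = 1.0 - 2.0 * (k + 0.5) / n_points
    theta = golden * k
    rs = np.sqrt(1.0 - zs**2)
    sphere = np.stack([rs * np.cos(theta), rs * np.sin(theta), zs], axis=1)
    tree = cKDTree(coords)
    areas = np.zeros(n)
    max_r = radii.max()
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neighbors = tree.query_ball_point(coords[i], radii[i] + max_r)
        neighbors = [j for j in neighbors if j != i]
        if neighbors:
            d = np.linalg.norm(pts[:, None, :] - coords[neighbors][None, :, :], axis=2)
            buried = (d < radii[neighbors][None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return areas


def _grid_cavities(structure: Structure, spacing: float, probe: float, pad_probe: float | None = None):
    """Shared grid machinery for volume and pocket detection.

    Returns (reachable, free, occupied, spacing) boolean voxel grids where
    ``reachable`` is the solvent region a probe can sweep from the outside.
    """
    coords = structure.coords
    radii = ff.vdw_radius_array(structure.elements)
    pad = radii.max() + max(probe, pad_probe or 0.0) + 2.0 * spacing + 1.0
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    tree = cKDTree(coords)
    # distance to nearest atom surface (approximate: use max radius shells)
    # exact per-atom radii: query nearest few atoms
    d, idx = tree.query(pts, k=min(8, len(coords)))
    d = np.atleast_2d(d.T).T
    idx = np.atleast_2d(idx.T).T
    surf = d - radii[idx]
    min_surf = surf.min(axis=1).reshape(gx.shape)
    occupied = min_surf <= 0.0
    free = ~occupied
    probe_open = min_surf > probe
    # exterior solvent: probe-open region connected to the box boundary
    lab, _ = ndimage.label(probe_open)
    edge_labels = set(np.unique(lab[0, :, :])) | set(np.unique(lab[-1, :, :]))
    edge_labels |= set(np.unique(lab[:, 0, :])) | set(np.unique(lab[:, -1, :]))
    edge_labels |= set(np.unique(lab[:, :, 0])) | set(np.unique(lab[:, :, -1]))
    edge_labels.discard(0)
    exterior_open = np.isin(lab, sorted(edge_labels))
    # sweep the probe: dilate exterior probe centers by the probe radius
    if probe > 0:
        r_vox = int(np.ceil(probe / spacing))
        ball = _ball_structuring_element(r_vox, probe / spacing)
        reachable = ndimage.binary_dilation(exterior_open, structure=ball) & free
    else:
        reachable = exterior_open
    return {
        "reachable": reachable,
        "free": free,
        "occupied": occupied,
        "spacing": spacing,
        "probe_open": probe_open,
        "exterior_open": exterior_open,
    }


def _ball_structuring_element(r_vox: int, r_frac: float) -> np.ndarray:
    g = np.mgrid[-r_vox : r_vox + 1, -r_vox : r_vox + 1, -r_vox : r_vox + 1]
    return (g[0] ** 2 + g[1] ** 2 + g[2] ** 2) <= r_frac**2


def molecular_volume_area(
    structure: Structure, probe: float = 1.4, spacing: float = 0.8
) -> tuple[float, float]:
    """(solvent-excluded volume A^3, solvent-accessible area A^2)."""
    if len(structure) == 0:
        return 0.0, 0.0
    g = _grid_cavities(structure, spacing, probe)
    volume = float((~g["reachable"]).sum() * g["spacing"] ** 3)
    area = float(_sasa(structure, probe=probe).sum())
    return volume, area


def find_pockets(
    structure: Structure,
    spacing: float = 0.8,
    probe: float = 1.4,
    surface_probe: float = 5.0,
    min_volume: float = 20.0,
    return_centroids: bool = False,
) -> list:
    """Grid-based cavity detection: (volume A^3, buried flag) per pocket.

    A buried pocket is a connected region where the solvent probe fits but
    cannot reach from bulk solvent (thin inter-helix films the probe cannot
    enter are not pockets).  Surface concavities — probe-accessible regions
    shielded from a large reference probe — are flagged non-buried.
    """
    if len(structure) == 0:
        return []
    g = _grid_cavities(structure, spacing, probe, pad_probe=surface_probe)
    h = g["spacing"]
    pad = ff.vdw_radius_array(structure.elements).max() + max(probe, surface_probe) + 2 * h + 1.0
    lo = structure.coords.min(axis=0) - pad

    def _collect(mask, buried, out):
        lab, n = ndimage.label(mask)
        for i in range(1, n + 1):
            where = lab == i
            vol = float(where.sum() * h**3)
            if vol >= min_volume:
                centroid = lo + h * np.mean(np.argwhere(where), axis=0)
                out.append((vol, buried, centroid))

    out: list = []
    _collect(g["probe_open"] & ~g["exterior_open"], True, out)
    # surface concavities: small-probe bulk solvent a large probe cannot sweep
    gb = _grid_cavities(structure, spacing, surface_probe, pad_probe=surface_probe)
    _collect(g["exterior_open"] & ~gb["reachable"], False, out)
    out.sort(key=lambda t: -t[0])
    if return_centroids:
        return out
    return [(v, b) for v, b, _ in out]


def helix_center_distance_score(bundle: BundleState) -> float:
    """Sum of distances from each helix geometric center to the bundle center."""
    if bundle.n_helices < 2:
        raise ValueError("need >= 2 helices")
    c = bundle.bundle_center
    return float(np.sum(np.linalg.norm(bundle.helix_centers - c, axis=1)))


# ----------------------------------------------------------------- orientation


def hydrophilic_exposure(
    bundle: BundleState, exposure_fraction: float = 0.25
) -> tuple[float, float]:
    """(A^2, A^2): exposed polar-group area in the membrane-embedded
    mid-third of the bundle.

    Term 1 counts groups that are at least ``exposure_fraction`` exposed
    relative to their standard Gly-X-Gly area; term 2 counts all
    charged/polar group exposure regardless of fraction.
    """
    st = bundle.structure
    areas = _sasa(st)
    point, normal = membrane_frame(bundle)
    ca_mask = st.atom_names == "CA"
    z = (st.coords[ca_mask] - point) @ normal
    zmin, zmax = z.min(), z.max()
    lo = zmin + (zmax - zmin) / 3.0
    hi = zmin + 2.0 * (zmax - zmin) / 3.0
    ca_res = st.res_seq[ca_mask]
    mid_residues = set(int(r) for r, zz in zip(ca_res, z) if lo <= zz <= hi)

    term1 = 0.0
    term2 = 0.0
    for rid in sorted(set(int(r) for r in st.res_seq)):
        mask = st.res_seq == rid
        rname = str(st.res_names[mask][0])
        if rname not in ff.POLAR_RESIDUES or rid not in mid_residues:
            continue
        if rname not in ff.GLY_X_GLY_POLAR_AREA:
            raise KeyError(f"no Gly-X-Gly reference area for residue type {rname}")
        group = ff.POLAR_GROUP_ATOMS[rname]
        gmask = mask & np.isin(st.atom_names, group)
        exposed = float(areas[gmask].sum())
        term2 += exposed
        if exposed >= exposure_fraction * ff.GLY_X_GLY_POLAR_AREA[rname]:
            term1 += exposed
    return term1, term2


def tilt_penalty(bundle: BundleState, max_tilt: float = 50.0, k: float = 1.0) -> float:
    """Sum over kink-split helix segments of k * max(0, tilt - max_tilt)."""
    axis = bundle.bundle_axis
    pen = 0.0
    for hid in range(1, bundle.n_helices + 1):
        for _, seg_axis in helix_axis_segments(bundle.helix(hid)):
            cosang = abs(float(np.dot(seg_axis, axis)))
            tilt = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            pen += k * max(0.0, tilt - max_tilt)
    return pen


def elevation_penalty(bundle: BundleState, k: float = 1.0) -> float:
    """k * sum of |helix-center elevation| from the membrane mid-plane."""
    return float(k * np.sum(np.abs(helix_elevations(bundle))))


def loop_span_penalty(
    bundle: BundleState,
    loop_lengths: list[int | None],
    rate: float = 3.2,
    k: float = 1.0,
) -> float:
    """Penalty when consecutive helix termini are farther apart than the
    loop between them can span (``rate`` A per loop residue)."""
    pen = 0.0
    for i in range(bundle.n_helices - 1):
        if i >= len(loop_lengths) or loop_lengths[i] is None:
            warnings.warn(f"no loop length for junction {i + 1}; skipped")
            continue
        n_loop = loop_lengths[i]
        a = bundle.helix(i + 1)
        b = bundle.helix(i + 2)
        d = float(np.linalg.norm(a.ca_coords()[-1] - b.ca_coords()[0]))
        pen += k * max(0.0, d - rate * n_loop) ** 2
    return pen


# -------------------------------------------------------------- ligand score


def _residue_atoms(st: Structure, res_seq: int, names) -> np.ndarray:
    idx = np.flatnonzero((st.res_seq == res_seq) & np.isin(st.atom_names, names))
    if len(idx) == 0:
        raise KeyError(f"residue {res_seq} atoms {names} not found")
    return idx


def serine_hbond_energy(bundle, ligand, serine_ids, params=None) -> float:
    """Best (most negative) single-serine hydrogen-bond energy between the
    ligand and the named serine residues (side-chain hydroxyl or backbone
    carbonyl, either donation direction)."""
    params = params or EnergyParams()
    st = bundle.structure
    best = 0.0
    for rid in serine_ids:
        e = 0.0
        # serine acceptors: OG + backbone O; serine donor: OG-HG
        acc = [int(i) for i in np.flatnonzero((st.res_seq == rid) & np.isin(st.atom_names, ("OG", "O")))]
        for d, h in ligand.donor_h:
            for a in acc:
                e += hbond_energy(ligand.coords[d], ligand.coords[h], st.coords[a], params)
        try:
            og = st.atom_index(rid, "OG")
            hg = st.atom_index(rid, "HG")
            for a in ligand.acceptors:
                e += hbond_energy(st.coords[og], st.coords[hg], ligand.coords[a], params)
        except KeyError:
            pass
        best = min(best, e)
    return best


def aspartate_interaction_energy(bundle, ligand, asp_id, params=None) -> float:
    """Electrostatic + hydrogen-bond energy between the ligand and the
    side-chain atoms of the named aspartate."""
    from .energy import COULOMB_K

    params = params or EnergyParams()
    st = bundle.structure
    side = _residue_atoms(st, asp_id, ("CB", "CG", "OD1", "OD2"))
    q_asp = ff.protein_charges(st.res_names[side], st.atom_names[side])
    e = 0.0
    for i, qi in zip(side, q_asp):
        if qi == 0.0:
            continue
        r = np.linalg.norm(ligand.coords - st.coords[i], axis=1)
        e += float(np.sum(COULOMB_K * ligand.charges * qi / (params.dielectric_eps * r * r)))
    od = _residue_atoms(st, asp_id, ("OD1", "OD2"))
    for d, h in ligand.donor_h:
        for a in od:
            e += hbond_energy(ligand.coords[d], ligand.coords[h], st.coords[a], params)
    return e


def aromatic_vdw_energy(bundle, ligand, phe_ids, params=None) -> float:
    """Plain Lennard-Jones energy between ligand aromatic atoms and the ring
    atoms of the named aromatic residues."""
    params = params or EnergyParams(softness=0.0)
    st = bundle.structure
    if len(ligand.aromatic_idx) == 0:
        return 0.0
    ring_idx = []
    for rid in phe_ids:
        rname = str(st.res_names[st.res_seq == rid][0])
        names = ff.AROMATIC_RING_ATOMS.get(rname)
        if names is None:
            raise KeyError(f"residue {rid} ({rname}) is not aromatic")
        ring_idx.extend(_residue_atoms(st, rid, names))
    lc = ligand.coords[ligand.aromatic_idx]
    le = ligand.elements[ligand.aromatic_idx]
    eps_l, sig_l = ff.lj_arrays(le)
    eps_p, sig_p = ff.lj_arrays(st.elements[ring_idx])
    d2 = np.sum((lc[:, None, :] - st.coords[ring_idx][None, :, :]) ** 2, axis=2)
    eps = np.sqrt(np.outer(eps_l, eps_p))
    sig = 0.5 * (sig_l[:, None] + sig_p[None, :])
    sr6 = (sig**2 / d2) ** 3
    return float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))


def ligand_score(
    bundle: BundleState,
    ligand,
    target_spec,
    weights: ScoreWeights | None = None,
) -> tuple[float, dict]:
    """Target-specific weighted ligand score with per-term breakdown.

    ``target_spec`` names the anchor residues (see :mod:`tmrepack.config`):
    serine ids, aspartate id, aromatic ids and the anchor restraint
    definitions evaluated on the current geometry.
    """
    weights = weights or ScoreWeights()
    w = weights.ligand_terms
    terms = {
        "serine_hbond": serine_hbond_energy(bundle, ligand, target_spec.serine_residues),
        "aspartate_elec_hbond": aspartate_interaction_energy(
            bundle, ligand, target_spec.aspartate_residue
        ),
        "restraints": _anchor_restraint_score(bundle, ligand, target_spec),
        "aromatic_vdw": aromatic_vdw_energy(bundle, ligand, target_spec.aromatic_residues),
    }
    score = sum(w[name] * val for name, val in terms.items())
    return float(score), terms


def _anchor_restraint_score(bundle, ligand, target_spec) -> float:
    st = bundle.structure
    e = 0.0
    for anchor in target_spec.anchors:
        pa = st.coords[[st.atom_index(r, a) for r, a in anchor.receptor_atoms]].mean(axis=0)
        if anchor.ligand_atoms:
            pb = ligand.coords[list(anchor.ligand_atoms)].mean(axis=0)
        else:
            pb = st.coords[[st.atom_index(r, a) for r, a in anchor.receptor_atoms_b]].mean(axis=0)
        e += flat_bottom(float(np.linalg.norm(pa - pb)), anchor.target, anchor.half_width, anchor.k)
    return e


def key_interaction_filter(
    bundle: BundleState,
    ligand,
    target_spec,
    hbond_max: float = -0.2,
    aromatic_vdw_max: float = -0.3,
    params=None,
) -> tuple[bool, list[str]]:
    """Pass/fail check for the two key-interaction criteria.

    Fails when the protonated-amine/aspartate salt bridge lacks a qualifying
    hydrogen bond (energy <= ``hbond_max``), or when the aromatic-aromatic
    vdW energy is above ``aromatic_vdw_max``.  Values exactly at a threshold
    pass.
    """
    params = params or EnergyParams()
    reasons = []
    st = bundle.structure
    od = _residue_atoms(st, target_spec.aspartate_residue, ("OD1", "OD2"))
    amine_dh = [(d, h) for d, h in ligand.donor_h if d in ligand.basic_n]
    best = 0.0
    for d, h in amine_dh:
        for a in od:
            best = min(
                best, hbond_energy(ligand.coords[d], ligand.coords[h], st.coords[a], params)
            )
    if not amine_dh or best > hbond_max:
        reasons.append("salt-bridge: no qualifying hydrogen bond to the aspartate")
    arom = aromatic_vdw_energy(bundle, ligand, target_spec.aromatic_residues, params)
    if len(ligand.aromatic_idx) == 0:
        reasons.append("aromatic vdW: ligand has no aromatic atoms")
    elif arom > aromatic_vdw_max:
        reasons.append(f"aromatic vdW energy {arom:.3f} above {aromatic_vdw_max}")
    return (len(reasons) == 0), reasons


# --------------------------------------------------------------------- totals


def score_model(
    bundle: BundleState,
    ligand=None,
    target_spec=None,
    weights: ScoreWeights | None = None,
    loop_lengths=None,
    grid_spacing: float = 0.8,
) -> ScoreReport:
    """Full ScoreReport for one model (protein terms always; ligand terms
    when a ligand and target spec are given)."""
    weights = weights or ScoreWeights()
    rep = ScoreReport()
    vol, area = molecular_volume_area(bundle.structure, spacing=grid_spacing)
    pockets = find_pockets(bundle.structure, spacing=grid_spacing)
    buried = [p for p in pockets if p[1]]
    rep.packing = {
        "volume": vol,
        "area": area,
        "buried_pocket_count": float(len(buried)),
        "buried_pocket_volume": float(sum(v for v, _ in buried)),
        "helix_center_distance": helix_center_distance_score(bundle),
    }
    t1, t2 = hydrophilic_exposure(bundle)
    if loop_lengths is None and target_spec is not None:
        loop_lengths = target_spec.loop_lengths
    rep.orientation = {
        "hydrophilic_exposure_major": t1,
        "hydrophilic_exposure_all": t2,
        "tilt_penalty": tilt_penalty(bundle),
        "elevation_penalty": elevation_penalty(bundle),
        "loop_span_penalty": (
            loop_span_penalty(bundle, loop_lengths) if loop_lengths else 0.0
        ),
        "anchor_penalty": (
            _receptor_anchor_penalty(bundle, target_spec) if target_spec is not None else 0.0
        ),
    }
    if ligand is not None and target_spec is not None:
        _, terms = ligand_score(bundle, ligand, target_spec, weights)
        rep.ligand = terms
    else:
        rep.ligand = {k: 0.0 for k in weights.ligand_terms}
    return total_score(rep, weights)[1]


def _receptor_anchor_penalty(bundle, target_spec) -> float:
    """Flat-bottom penalty on the receptor-side anchor distance (e.g. the
    aspartate-to-serines window)."""
    st = bundle.structure
    e = 0.0
    for anchor in target_spec.receptor_anchors:
        pa = st.coords[[st.atom_index(r, a) for r, a in anchor.receptor_atoms]].mean(axis=0)
        pb = st.coords[[st.atom_index(r, a) for r, a in anchor.receptor_atoms_b]].mean(axis=0)
        e += flat_bottom(float(np.linalg.norm(pa - pb)), anchor.target, anchor.half_width, anchor.k)
    return e


def total_score(report: ScoreReport, weights: ScoreWeights | None = None) -> tuple[float, ScoreReport]:
    """Weighted sum of the three sub-scores (lower is better)."""
    weights = weights or ScoreWeights()
    report.packing_score = float(
        sum(weights.packing_terms.get(k, 0.0) * v for k, v in report.packing.items())
    )
    report.orientation_score = float(
        sum(weights.orientation_terms.get(k, 0.0) * v for k, v in report.orientation.items())
    )
    report.ligand_score = float(
        sum(weights.ligand_terms.get(k, 0.0) * v for k, v in report.ligand.items())
    )
    report.total_score = float(
        weights.top_level["packing"] * report.packing_score
        + weights.top_level["orientation"] * report.orientation_score
        + weights.top_level["ligand"] * report.ligand_score
    )
    return report.total_score, report


def default_model_score(record) -> float:
    """Checkpoint score used by the pipeline: packing + orientation."""
    rep = score_model(record.bundle)
    return rep.packing_score + rep.orientation_score


def fit_zscore_weights(reports: list[ScoreReport]) -> ScoreWeights:
    """Normalize each term by its spread over an ensemble (z-score scaling),
    keeping unit top-level weights."""
    weights = ScoreWeights()
    for group, terms in (
        ("packing_terms", [r.packing for r in reports]),
        ("orientation_terms", [r.orientation for r in reports]),
        ("ligand_terms", [r.ligand for r in reports]),
    ):
        wdict = getattr(weights, group)
        for key in wdict:
            vals = np.array([t.get(key, 0.0) for t in terms])
            sd = vals.std()
            wdict[key] = 1.0 / sd if sd > 1e-12 else 0.0
    return weights
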