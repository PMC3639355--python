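"""Deterministic synthetic fixtures: ideal helix bundles, graded decoys and
small-molecule ligands.

Everything here is generated from internal coordinates or packaged SMILES at
run time, so tests and demos never download anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bundle import BundleState, HelixRigidVariables, set_rigid_variables
from .geometry import nerf_place, rot_z
from .structure import Structure

# Ideal backbone geometry (bond lengths Angstrom, angles degrees)
_BB = {
    "n_ca": 1.458,
    "ca_c": 1.525,
    "c_n": 1.329,
    "c_o": 1.231,
    "n_h": 1.010,
    "ang_n_ca_c": 111.2,
    "ang_ca_c_n": 116.2,
    "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8,
}
PHI_IDEAL = -57.0
PSI_IDEAL = -47.0
OMEGA = 180.0

# Side-chain z-matrix entries: atom -> (element, ref atoms (a, b, c), bond,
# angle, torsion).  Reference names resolve within the same residue, "-C"
# means the preceding residue's C.  Chirality of CB placement was verified
# against L-amino acid geometry.
_SIDECHAINS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [("CB", "C", ("N", "C", "CA"), 1.521, 110.4, 122.6)],
    "SER": [
        ("CB", "C", ("N", "C", "CA"), 1.530, 110.4, 122.6),
        ("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, -65.0),
        ("HG", "H", ("CA", "CB", "OG"), 0.960, 109.5, 180.0),
    ],
    "ASP": [
        ("CB", "C", ("N", "C", "CA"), 1.530, 110.4, 122.6),
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, -65.0),
        ("OD1", "O", ("CA", "CB", "CG"), 1.250, 118.4, -20.0),
        ("OD2", "O", ("CA", "CB", "CG"), 1.250, 118.4, 160.0),
    ],
    "PHE": [
        ("CB", "C", ("N", "C", "CA"), 1.530, 110.4, 122.6),
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, -65.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.391, 120.8, 90.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.391, 120.8, -90.0),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.391, 120.1, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.391, 120.1, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.391, 120.0, 0.0),
    ],
    "LYS": [
        ("CB", "C", ("N", "C", "CA"), 1.530, 110.4, 122.6),
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, -65.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
        ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
        ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, 180.0),
    ],
}

_AA3 = {
    "A": "ALA",
    "G": "GLY",
    "S": "SER",
    "D": "ASP",
    "F": "PHE",
    "K": "LYS",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic helix bundle."""

    n_helices: int = 7
    helix_length: int = 18
    ring_radius: float = 10.5
    sequence: str | None = None  # one-letter; None -> poly-Ala
    first_resid: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.ring_radius <= 0 or self.helix_length < 6 or self.n_helices < 1:
            raise ValueError(f"invalid fixture spec: {self}")


def build_ideal_helix(
    sequence: str,
    first_resid: int = 1,
    phi: float | np.ndarray = PHI_IDEAL,
    psi: float | np.ndarray = PSI_IDEAL,
) -> Structure:
    """Build an ideal alpha-helix from one-letter ``sequence`` using standard
    internal coordinates.  Per-residue phi/psi arrays allow kinked helices.
    Returns a structure roughly aligned with +z, centered at the origin.
    """
    n = len(sequence)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (n,))
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (n,))
    names, elements, res_seq, res_names, coords = [], [], [], [], []

    # seed atoms for the NeRF chain
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_BB["n_ca"], 0.0, 0.0])
    ang = np.deg2rad(_BB["ang_n_ca_c"])
    c0 = ca0 + _BB["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    bb = {}  # residue index -> dict of backbone coords

    for i in range(n):
        if i == 0:
            bb[0] = {"N": n0, "CA": ca0, "C": c0}
        else:
            prev = bb[i - 1]
            nn = nerf_place(prev["N"], prev["CA"], prev["C"], _BB["c_n"], _BB["ang_ca_c_n"], psi[i - 1])
            ca = nerf_place(prev["CA"], prev["C"], nn, _BB["n_ca"], _BB["ang_c_n_ca"], OMEGA)
            cc = nerf_place(prev["C"], nn, ca, _BB["ca_c"], _BB["ang_n_ca_c"], phi[i])
            bb[i] = {"N": nn, "CA": ca, "C": cc}

    for i, one in enumerate(sequence):
        res3 = _AA3.get(one.upper())
        if res3 is None:
            raise ValueError(f"unsupported fixture residue '{one}' (supported: {sorted(_AA3)})")
        rid = first_resid + i
        r = dict(bb[i])
        # carbonyl O off the C, trans to the next N direction
        r["O"] = nerf_place(r["N"], r["CA"], r["C"], _BB["c_o"], _BB["ang_ca_c_o"], psi[i] + 180.0)
        atoms = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
        if i > 0:
            # amide H on the N-CA / N-C(i-1) bisector
            prev_c = bb[i - 1]["C"]
            u = r["N"] - prev_c
            v = r["N"] - r["CA"]
            h = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            r["H"] = r["N"] + _BB["n_h"] * h / np.linalg.norm(h)
            atoms.append(("H", "H"))
        lookup = {"-C": bb[i - 1]["C"] if i > 0 else None}
        for name, element, (a, b, c), bond, angle, torsion in _SIDECHAINS[res3]:
            refs = [lookup[x] if x.startswith("-") else r[x] for x in (a, b, c)]
            r[name] = nerf_place(*refs, bond, angle, torsion)
            atoms.append((name, element))
        for name, element in atoms:
            names.append(name)
            elements.append(element)
            res_seq.append(rid)
            res_names.append(res3)
            coords.append(r[name])

    st = Structure(np.array(coords), names, elements, res_seq, res_names)
    # center and align the backbone principal axis exactly with +z (the same
    # axis definition HelixSegment.axis uses, so fixture axes are exact)
    from .geometry import principal_axis
    from .structure import BACKBONE_ATOMS

    ca = st.coords[st.atom_names == "CA"]
    ax = principal_axis(st.coords[np.isin(st.atom_names, BACKBONE_ATOMS)])
    if np.dot(ax, ca[-1] - ca[0]) < 0:
        ax = -ax
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(ax, z)
    s = np.linalg.norm(v)
    if s > 1e-12:
        c = np.dot(ax, z)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        st.coords = st.coords @ rot.T
    st.coords -= st.coords.mean(axis=0)
    return st


def _assemble_bundle(
    seqs: list[str],
    ring_radius: float,
    include_center: bool,
    first_resid: int = 1,
    min_contact: float = 3.0,
) -> BundleState:
    """Place ideal helices (optionally one central + ring) with alternating
    antiparallel orientation; raise on inter-helix clashes."""
    n = len(seqs)
    positions = []
    n_ring = n - 1 if include_center else n
    if include_center:
        positions.append((0.0, 0.0))
    for h in range(n_ring):
        theta = 360.0 * h / n_ring
        positions.append(
            (ring_radius * np.cos(np.deg2rad(theta)), ring_radius * np.sin(np.deg2rad(theta)))
        )
    parts, slices, spans = [], [], []
    offset = 0
    rid = first_resid
    for h in range(n):
        helix = build_ideal_helix(seqs[h], first_resid=rid)
        if h % 2 == 1:  # antiparallel: flip about x
            helix.coords = helix.coords @ np.diag([1.0, -1.0, -1.0])
        x, y = positions[h]
        theta = np.degrees(np.arctan2(y, x))
        helix.coords = helix.coords @ rot_z(theta).T + np.array([x, y, 0.0])
        # pin every helix center exactly onto the z = 0 mid-plane so the
        # ideal bundle scores zero on all orientation penalties by construction
        helix.coords[:, 2] -= helix.coords[:, 2].mean()
        parts.append(helix)
        slices.append(slice(offset, offset + len(helix)))
        spans.append((rid, rid + len(seqs[h]) - 1))
        offset += len(helix)
        rid += len(seqs[h]) + 5  # leave a notional 5-residue loop gap

    st = Structure.concat(parts)
    bundle = BundleState(st, slices, spans)
    from scipy.spatial import cKDTree

    for i in range(n):
        for j in range(i + 1, n):
            hi, hj = bundle.helix(i + 1), bundle.helix(j + 1)
            a = hi.structure.coords[hi.structure.heavy_mask]
            b = hj.structure.coords[hj.structure.heavy_mask]
            d = cKDTree(a).query(b, k=1)[0].min()
            if d < min_contact:
                raise ValueError(
                    f"infeasible ring radius {ring_radius}: helices {i + 1}/{j + 1} "
                    f"clash at {d:.2f} A"
                )
    return bundle


def make_ideal_bundle(spec: FixtureSpec = FixtureSpec()) -> BundleState:
    """Ideal bundle: straight helices, axes parallel to z, alternating
    antiparallel orientation; 7+ helices pack as one central helix plus a
    ring so the core is tight, smaller bundles as a plain ring."""
    spec.validate()
    seqs = [spec.sequence or "A" * spec.helix_length for _ in range(spec.n_helices)]
    return _assemble_bundle(seqs, spec.ring_radius, include_center=spec.n_helices >= 7,
                            first_resid=spec.first_resid)


def orient_residue_inward(bundle: BundleState, helix_id: int, res_seq: int) -> BundleState:
    """Spin a helix about its own axis so the named residue's CB points at
    the bundle center (used to build binding-pocket fixtures)."""
    st = bundle.structure
    ca = st.coords[st.atom_index(res_seq, "CA")]
    cb = st.coords[st.atom_index(res_seq, "CB")]
    sl = bundle.helix_slices[helix_id - 1]
    center = st.coords[sl].mean(axis=0)
    axis = bundle.helix(helix_id).axis()

    def flatten(v):
        return v - np.dot(v, axis) * axis

    current = flatten(cb - ca)
    target = flatten(bundle.bundle_center - center)
    cur = current / np.linalg.norm(current)
    tgt = target / np.linalg.norm(target)
    ang = np.degrees(np.arctan2(np.dot(np.cross(cur, tgt), axis), np.dot(cur, tgt)))
    from .geometry import rotation_about_axis

    new = bundle.copy()
    r = rotation_about_axis(axis, ang)
    new.structure.coords[sl] = (new.structure.coords[sl] - center) @ r.T + center
    return new


def make_pocket_bundle(ring_radius: float = 11.5, helix_length: int = 18):
    """Six-helix ring with an open central pocket lined by an aspartate, a
    serine and a phenylalanine, all facing the lumen.

    Returns the bundle; use :func:`pocket_target_spec` for the matching
    target specification.
    """
    mid = helix_length // 2
    seqs = ["A" * helix_length for _ in range(6)]

    def with_residue(seq, one):
        return seq[:mid] + one + seq[mid + 1:]

    seqs[0] = with_residue(seqs[0], "D")
    seqs[1] = with_residue(seqs[1], "S")
    seqs[5] = with_residue(seqs[5], "F")
    bundle = _assemble_bundle(seqs, ring_radius, include_center=False)
    for hid in (1, 2, 6):
        span = bundle.spans[hid - 1]
        rid = span[0] + mid
        bundle = orient_residue_inward(bundle, hid, rid)
    return bundle


def pocket_target_spec(bundle: BundleState):
    """TargetSpec for the pocket fixture bundle (anchor window measured from
    the built geometry so the restraint starts satisfied)."""
    from .config import AcceptanceCriteria, AnchorSpec, TargetSpec

    st = bundle.structure
    rid_of = {}
    for rid in set(int(r) for r in st.res_seq):
        rname = str(st.res_names[st.res_seq == rid][0])
        if rname in ("ASP", "SER", "PHE"):
            rid_of[rname] = rid
    od = st.coords[
        [st.atom_index(rid_of["ASP"], "OD1"), st.atom_index(rid_of["ASP"], "OD2")]
    ].mean(axis=0)
    og = st.coords[st.atom_index(rid_of["SER"], "OG")]
    d = float(np.linalg.norm(od - og))
    return TargetSpec(
        name="pocket_fixture",
        helix_spans=list(bundle.spans),
        tether_residues=[[] for _ in bundle.spans],
        serine_residues=[rid_of["SER"]],
        aspartate_residue=rid_of["ASP"],
        aromatic_residues=[rid_of["PHE"]],
        receptor_anchors=[
            AnchorSpec(
                receptor_atoms=[(rid_of["ASP"], "OD1"), (rid_of["ASP"], "OD2")],
                receptor_atoms_b=[(rid_of["SER"], "OG")],
                target=round(d, 1),
                half_width=2.0,
            )
        ],
        acceptance=AcceptanceCriteria(),
    )


def make_kinked_helix(length: int = 20, kink_at: int = 10, kink_deg: float = 30.0) -> Structure:
    """Straight helix with a localized backbone kink (proline-like) at residue
    ``kink_at`` (1-based), produced by perturbing phi/psi of two residues."""
    phi = np.full(length, PHI_IDEAL)
    psi = np.full(length, PSI_IDEAL)
    # a single-psi break of ~1.4x the target angle bends the axis by ~kink_deg
    psi[kink_at - 1] -= 1.4 * kink_deg
    return build_ideal_helix("A" * length, phi=phi, psi=psi)


def make_decoy_set(
    bundle: BundleState,
    amplitudes: list[float],
    n_per_level: int,
    seed: int = 0,
) -> list[tuple[float, BundleState]]:
    """Graded decoys: randomize helix placements at each amplitude level
    (fractions of the default perturbation amplitudes)."""
    from .perturb import PerturbAmplitudes, randomize_bundle

    out = []
    rng = np.random.default_rng(seed)
    for level in amplitudes:
        amp = PerturbAmplitudes(
            max_translation=5.0 * level, max_tilt=20.0 * level, max_spin=30.0 * level
        )
        for _ in range(n_per_level):
            sub = int(rng.integers(0, 2**31 - 1))
            out.append((level, randomize_bundle(bundle, amp, seed=sub)))
    return out


# ------------------------------------------------------------------- ligands

LIGAND_SMILES = {
    "toy_cation": "[NH4+]",
    "toy_catechol_amine": "[NH3+]CCc1ccc(O)c(O)c1",  # protonated dopamine
    "R-NPA": "CCC[NH+]1CCc2cccc3c2[C@H]1Cc1ccc(O)c(O)c1-3",
    "S-cyanopindolol": "CC(C)(C)[NH2+]C[C@H](O)COc1cccc2[nH]c(C#N)cc12",
}

_EMBED_SEED = 2013


def make_ligand_fixture(name: str, seed: int = _EMBED_SEED):
    """Build a 3D ligand conformer from packaged SMILES (protonation
    pre-assigned in the SMILES).  Returns an RDKit mol with one conformer,
    explicit hydrogens, Gasteiger charges and aromatic perception done.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    if name not in LIGAND_SMILES:
        raise KeyError(f"unknown ligand fixture '{name}' (have: {sorted(LIGAND_SMILES)})")
    mol = Chem.MolFromSmiles(LIGAND_SMILES[name])
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"3D embedding failed for {name}")
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    AllChem.ComputeGasteigerCharges(mol)
    return mol
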