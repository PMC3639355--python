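"""Staged Monte Carlo optimization of a receptor/ligand complex.

Four stages release degrees of freedom stepwise (rigid helices + rigid
ligand first, then ligand torsions and side chains, finally backbone
torsions), soften the van der Waals potential from capped-soft to plain
6-12, and ramp conserved-residue tethers down to zero.  Move classes are
drawn with biased frequencies (ligand : pocket : helix : rest =
100 : 50 : 20 : 2) and evaluated with exact move-local energy deltas.
Model pools are filtered at two score checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bundle import BundleState
from .energy import (
    EnergyParams,
    EnergySystem,
    RestraintSet,
    anchor_restraint_energy,
    detect_bonds,
    group_nonbonded_energy,
    hbond_sum,
    tether_energy,
    torsion_strain,
)
from .forcefield import protein_charges
from .geometry import rotation_about_axis
from .ligands import LigandConformer, ligand_structure_arrays

KB = 0.0019872041  # kcal/mol/K

MOVE_CLASSES = ("ligand", "binding_pocket", "helix_positional", "remaining_protein")


@dataclass(frozen=True)
class SamplingWeights:
    """Relative move-class selection frequencies."""

    ligand: float = 100.0
    binding_pocket: float = 50.0
    helix_positional: float = 20.0
    remaining_protein: float = 2.0

    def as_dict(self) -> dict[str, float]:
        return {
            "ligand": self.ligand,
            "binding_pocket": self.binding_pocket,
            "helix_positional": self.helix_positional,
            "remaining_protein": self.remaining_protein,
        }


@dataclass(frozen=True)
class StageConfig:
    stage_id: int
    free_classes: tuple[str, ...]  # from {"helix", "ligand_rigid", "ligand_torsion", "side_chain", "backbone"}
    softness: float
    tether_scale: tuple[float, float]  # linear ramp start -> end over the stage
    n_steps: int
    t_start: float = 600.0
    t_end: float = 300.0
    post_filter: bool = False
    vdw_cap: float = 2.0
    # proposal magnitudes (sigma of the Gaussian draws)
    step_translation: float = 0.5  # A
    step_rotation: float = 3.0  # deg (helix tilt/spin, ligand rotation)
    step_torsion: float = 15.0  # deg
    pocket_redefine_every: int = 250  # accepted moves


def default_stages(scale: float = 1.0) -> list[StageConfig]:
    """Desk-scale defaults; ``scale`` multiplies the step budgets."""
    b = lambda n: max(1, int(round(n * scale)))
    return [
        StageConfig(1, ("helix", "ligand_rigid"), 1.0, (1.0, 1.0), b(2000), post_filter=True),
        StageConfig(2, ("helix", "ligand_rigid", "ligand_torsion", "side_chain"), 0.6, (1.0, 0.7), b(5000)),
        StageConfig(
            3, ("helix", "ligand_rigid", "ligand_torsion", "side_chain"), 0.3, (0.7, 0.3), b(10000), post_filter=True
        ),
        StageConfig(
            4,
            ("helix", "ligand_rigid", "ligand_torsion", "side_chain", "backbone"),
            0.0,
            (0.3, 0.0),
            b(20000),
        ),
    ]


def validate_stages(stages: list[StageConfig]) -> None:
    prev: set[str] = set()
    prev_soft = np.inf
    for s in stages:
        free = set(s.free_classes)
        if not prev.issubset(free):
            raise ValueError(f"free variable classes must grow monotonically (stage {s.stage_id})")
        if s.softness > prev_soft:
            raise ValueError(f"softness schedule must be non-increasing (stage {s.stage_id})")
        prev, prev_soft = free, s.softness
    if stages and stages[-1].tether_scale[1] != 0.0:
        raise ValueError("final stage must end with tether scale 0")


# --------------------------------------------------------------------- state


class ComplexState:
    """Mutable receptor(+ligand) state for the optimizer.

    Combines the bundle atoms and the ligand atoms into one
    :class:`EnergySystem`; ligand atoms occupy the trailing index block.
    """

    def __init__(self, bundle: BundleState, ligand: LigandConformer | None = None):
        self.bundle = bundle.copy()
        self.ligand = ligand.copy() if ligand is not None else None
        st = self.bundle.structure
        n_prot = len(st)
        coords = st.coords
        elements = st.elements
        charges = protein_charges(st.res_names, st.atom_names)
        bonds = detect_bonds(coords, elements)
        if self.ligand is not None:
            lc = self.ligand.coords
            coords = np.vstack([coords, lc])
            elements = np.concatenate([elements, self.ligand.elements])
            charges = np.concatenate([charges, self.ligand.charges])
            bonds = bonds + [(i + n_prot, j + n_prot) for i, j in self.ligand.bonds]
        self.system = EnergySystem(coords, elements, charges, bonds)
        self.n_protein = n_prot
        self.ligand_offset = n_prot
        # share coordinate storage: bundle/ligand views into system.coords
        self.system.coords[:n_prot] = st.coords
        st.coords = self.system.coords[:n_prot]
        if self.ligand is not None:
            self.system.coords[n_prot:] = self.ligand.coords
            self.ligand.coords = self.system.coords[n_prot:]
        self._torsion_index = self._index_protein_torsions()

    @property
    def coords(self) -> np.ndarray:
        return self.system.coords

    def snapshot(self) -> np.ndarray:
        return self.system.coords.copy()

    def restore(self, coords: np.ndarray) -> None:
        self.system.coords[:] = coords

    def detach(self) -> tuple[BundleState, LigandConformer | None]:
        """Deep-copied bundle/ligand decoupled from the shared arrays."""
        b = self.bundle.copy()
        b.structure.coords = self.system.coords[: self.n_protein].copy()
        lig = None
        if self.ligand is not None:
            lig = self.ligand.copy()
            lig.coords = self.system.coords[self.n_protein:].copy()
        return b, lig

    # ------------------------------------------------------------- torsions

    def _index_protein_torsions(self):
        """Per-residue side-chain and backbone torsion definitions.

        Each entry: (axis atom a, axis atom b, moved atom indices).
        """
        st = self.bundle.structure
        side: dict[int, list] = {}
        backbone: dict[int, list] = {}
        chi_chains = {
            "SER": ["CB", "OG"],
            "ASP": ["CB", "CG"],
            "PHE": ["CB", "CG"],
            "LYS": ["CB", "CG", "CD", "CE"],
        }
        for hidx, sl in enumerate(self.bundle.helix_slices):
            res_in_helix = sorted(set(int(r) for r in st.res_seq[sl]))
            helix_atoms = np.arange(sl.start, sl.stop)
            for pos, rid in enumerate(res_in_helix):
                rmask = st.res_seq == rid
                ridx = np.flatnonzero(rmask)
                names = {str(st.atom_names[i]): i for i in ridx}
                rname = str(st.res_names[ridx[0]])
                # side-chain chis: rotate atoms beyond each chain bond
                chain = ["CA"] + chi_chains.get(rname, [])
                sc_atoms = [i for i in ridx if str(st.atom_names[i]) not in ("N", "H", "CA", "C", "O")]
                entries = []
                for k in range(len(chain) - 1):
                    a, b = names.get(chain[k]), names.get(chain[k + 1])
                    if a is None or b is None:
                        continue
                    order = {n: i for i, n in enumerate(chain)}
                    moved = [
                        i
                        for i in sc_atoms
                        if str(st.atom_names[i]) not in order
                        or order[str(st.atom_names[i])] > k + 1
                    ]
                    if moved:
                        entries.append((a, b, np.array(moved)))
                if entries:
                    side[rid] = entries
                # backbone phi/psi: rotate everything downstream within the helix
                later = helix_atoms[st.res_seq[helix_atoms] > rid]
                bb = []
                if "N" in names and "CA" in names:
                    moved = np.concatenate(
                        [[i for i in ridx if str(st.atom_names[i]) not in ("N", "H")], later]
                    ).astype(int)
                    bb.append((names["N"], names["CA"], moved))
                if "CA" in names and "C" in names and pos < len(res_in_helix) - 1:
                    moved = np.concatenate([[names["O"]], later]).astype(int)
                    bb.append((names["CA"], names["C"], moved))
                if bb:
                    backbone[rid] = bb
        return {"side": side, "backbone": backbone}


def binding_pocket_residues(
    bundle: BundleState, ligand_coords: np.ndarray, cutoff: float = 7.0
) -> set[int]:
    """Residues with any heavy atom within ``cutoff`` of any ligand heavy atom."""
    if cutoff <= 0 or len(ligand_coords) == 0:
        return set()
    from scipy.spatial import cKDTree

    st = bundle.structure
    heavy = st.heavy_mask
    tree = cKDTree(np.asarray(ligand_coords, dtype=float))
    d = tree.query(st.coords[heavy], k=1)[0]
    hits = st.res_seq[heavy][d <= cutoff]
    return set(int(r) for r in hits)


def draw_move_class(
    rng: np.random.Generator, weights: SamplingWeights, available: tuple[str, ...]
) -> str:
    w = weights.as_dict()
    probs = np.array([w[c] for c in available], dtype=float)
    probs /= probs.sum()
    return available[int(rng.choice(len(available), p=probs))]


# ----------------------------------------------------------------- optimizer


@dataclass
class McTrace:
    energies: list = field(default_factory=list)
    accepted: list = field(default_factory=list)
    n_proposed: int = 0
    n_accepted: int = 0


def _total_mc_energy(state: ComplexState, params, restraints, tether_scale, lig_hbond, torsions):
    from .energy import electrostatic_energy, vdw_energy

    e = vdw_energy(state.system, params) + electrostatic_energy(state.system, params)
    e += tether_energy(state.system, restraints, tether_scale)
    e += anchor_restraint_energy(state.system, restraints)
    if lig_hbond is not None:
        e += hbond_sum(state.system, lig_hbond[0], lig_hbond[1], params)
    if torsions:
        e += torsion_strain(state.system.coords, torsions)
    return e


def mc_optimize(
    state: ComplexState,
    stage: StageConfig,
    weights: SamplingWeights = SamplingWeights(),
    seed: int = 0,
    restraints: RestraintSet | None = None,
) -> tuple[ComplexState, McTrace]:
    """Metropolis Monte Carlo over the stage's free variable classes.

    Returns the best-energy state visited and a per-step trace.  Identical
    seeds yield bit-identical trajectories.
    """
    rng = np.random.default_rng(seed)
    restraints = restraints or RestraintSet()
    trace = McTrace()
    if stage.n_steps == 0:
        return state, trace

    params = EnergyParams(softness=stage.softness, vdw_cap=stage.vdw_cap)
    has_ligand = state.ligand is not None

    # ligand hbond pairs (ligand donors vs protein acceptors and vice versa)
    lig_hbond = None
    torsions = []
    if has_ligand:
        off = state.ligand_offset
        donors = [(d + off, h + off) for d, h in state.ligand.donor_h]
        st = state.bundle.structure
        prot_acc = [int(i) for i in np.flatnonzero(st.elements == "O")]
        lig_hbond = (donors, prot_acc)
        torsions = [
            (i + off, j + off, k + off, l + off, v)
            for (i, j, k, l, v) in state.ligand.torsion_quads()
        ]

    # map stage free classes onto move classes
    available = []
    if has_ligand and ("ligand_rigid" in stage.free_classes or "ligand_torsion" in stage.free_classes):
        available.append("ligand")
    if "side_chain" in stage.free_classes or "backbone" in stage.free_classes:
        available.extend(["binding_pocket", "remaining_protein"])
    if "helix" in stage.free_classes:
        available.append("helix_positional")
    available = tuple(available)
    if not available:
        return state, trace

    pocket: set[int] = set()
    if has_ligand:
        pocket = binding_pocket_residues(
            state.bundle, state.system.coords[state.ligand_offset:][state.ligand.heavy_mask]
        )

    def current_energy():
        return _total_mc_energy(state, params, restraints, tether_scale(0), lig_hbond, torsions)

    def tether_scale(step):
        f = step / max(1, stage.n_steps)
        a, b = stage.tether_scale
        return a + (b - a) * f

    def local_energy(group, scale):
        e = group_nonbonded_energy(state.system, params, group)
        gset = set(int(g) for g in group)
        for t in restraints.tethers:
            if t.atom_index in gset and scale != 0.0:
                e += t.k * scale * float(np.sum((state.system.coords[t.atom_index] - t.reference) ** 2))
        e += anchor_restraint_energy(state.system, restraints)
        if lig_hbond is not None:
            e += hbond_sum(state.system, lig_hbond[0], lig_hbond[1], params)
        if torsions:
            e += torsion_strain(state.system.coords, torsions)
        return e

    sl_lig = slice(state.ligand_offset, len(state.system)) if has_ligand else None
    energy = current_energy()
    best_energy = energy
    best_coords = state.snapshot()

    for step in range(stage.n_steps):
        frac = step / max(1, stage.n_steps - 1)
        temp = stage.t_start * (stage.t_end / stage.t_start) ** frac
        scale = tether_scale(step)
        cls = draw_move_class(rng, weights, available)
        group = None

        # --- propose
        if cls == "ligand":
            choices = []
            if "ligand_rigid" in stage.free_classes:
                choices.extend(["trans", "rot"])
            if "ligand_torsion" in stage.free_classes and state.ligand.n_rotatable > 0:
                choices.append("torsion")
            kind = choices[int(rng.integers(len(choices)))]
            if kind == "torsion":
                t = int(rng.integers(state.ligand.n_rotatable))
                rot = state.ligand.rotatable[t]
                j, k = rot["bond"]
                group = rot["downstream"] + state.ligand_offset
                old = state.system.coords[group].copy()
                e0 = local_energy(group, scale)
                axis = state.system.coords[k + state.ligand_offset] - state.system.coords[j + state.ligand_offset]
                r = rotation_about_axis(axis, rng.normal(0.0, stage.step_torsion))
                pivot = state.system.coords[k + state.ligand_offset]
                state.system.coords[group] = (state.system.coords[group] - pivot) @ r.T + pivot
            else:
                group = np.arange(sl_lig.start, sl_lig.stop)
                old = state.system.coords[group].copy()
                e0 = local_energy(group, scale)
                if kind == "trans":
                    state.system.coords[group] += rng.normal(0.0, stage.step_translation, 3)
                else:
                    center = state.system.coords[group].mean(axis=0)
                    axis = rng.normal(size=3)
                    r = rotation_about_axis(axis, rng.normal(0.0, stage.step_rotation))
                    state.system.coords[group] = (state.system.coords[group] - center) @ r.T + center
        elif cls == "helix_positional":
            hid = int(rng.integers(1, state.bundle.n_helices + 1))
            hsl = state.bundle.helix_slices[hid - 1]
            group = np.arange(hsl.start, hsl.stop)
            old = state.system.coords[group].copy()
            e0 = local_energy(group, scale)
            kind = int(rng.integers(4))
            coords = state.system.coords[group]
            center = coords.mean(axis=0)
            z = state.bundle.frame_axes[:, 2]
            if kind == 0:  # in-plane translation
                v = rng.normal(0.0, stage.step_translation, 3)
                v -= np.dot(v, z) * z
                state.system.coords[group] = coords + v
            elif kind == 1:  # along-axis translation
                state.system.coords[group] = coords + rng.normal(0.0, stage.step_translation) * z
            else:
                axis_h = state.bundle.helix(hid).axis()
                if kind == 2:  # tilt about center, random perpendicular axis
                    perp = np.cross(axis_h, rng.normal(size=3))
                    perp /= np.linalg.norm(perp)
                    r = rotation_about_axis(perp, rng.normal(0.0, stage.step_rotation))
                else:  # spin about own axis
                    r = rotation_about_axis(axis_h, rng.normal(0.0, stage.step_rotation))
                state.system.coords[group] = (coords - center) @ r.T + center
        else:  # side-chain / backbone torsion move
            if cls == "binding_pocket":
                candidates = sorted(pocket)
            else:
                in_pocket = pocket
                candidates = [
                    r for r in state._torsion_index["side"] if r not in in_pocket
                ]
                if "backbone" in stage.free_classes:
                    candidates += [
                        r for r in state._torsion_index["backbone"] if r not in in_pocket
                    ]
                candidates = sorted(set(candidates))
            pools = []
            for rid in candidates:
                if rid in state._torsion_index["side"]:
                    pools.extend(state._torsion_index["side"][rid])
                if "backbone" in stage.free_classes and rid in state._torsion_index["backbone"]:
                    pools.extend(state._torsion_index["backbone"][rid])
            if not pools:
                trace.n_proposed += 1
                trace.energies.append(energy)
                trace.accepted.append(False)
                continue
            a, bb, moved = pools[int(rng.integers(len(pools)))]
            group = moved
            old = state.system.coords[group].copy()
            e0 = local_energy(group, scale)
            axis = state.system.coords[bb] - state.system.coords[a]
            r = rotation_about_axis(axis, rng.normal(0.0, stage.step_torsion))
            pivot = state.system.coords[bb]
            state.system.coords[group] = (state.system.coords[group] - pivot) @ r.T + pivot

        e1 = local_energy(group, scale)
        delta = e1 - e0
        trace.n_proposed += 1
        accept = delta <= 0 or rng.random() < np.exp(-delta / (KB * temp))
        if accept:
            energy += delta
            trace.n_accepted += 1
            if has_ligand and trace.n_accepted % stage.pocket_redefine_every == 0:
                pocket = binding_pocket_residues(
                    state.bundle,
                    state.system.coords[state.ligand_offset:][state.ligand.heavy_mask],
                )
            if energy < best_energy:
                best_energy = energy
                best_coords = state.snapshot()
        else:
            state.system.coords[group] = old
        trace.energies.append(energy)
        trace.accepted.append(accept)

    state.restore(best_coords)
    return state, trace


# ------------------------------------------------------------------ pipeline


@dataclass
class ModelRecord:
    model_id: int
    seed: int
    bundle: BundleState
    ligand: LigandConformer | None
    energy: float = np.nan
    report: object = None  # ScoreReport
    stage_reached: int = 0


def select_by_threshold(
    models: list[ModelRecord],
    score_key,
    threshold: float | None = None,
    percentile: float | None = None,
) -> list[ModelRecord]:
    """Deterministic subset of models by score (lower is better).

    Absolute ``threshold`` keeps scores <= threshold.  ``percentile`` p keeps
    the best ceil(p/100 * n) models, with p = 0 keeping the single best.
    Ties break by model id.
    """
    if (threshold is None) == (percentile is None):
        raise ValueError("provide exactly one of threshold/percentile")
    scored = sorted(models, key=lambda m: (score_key(m), m.model_id))
    if threshold is not None:
        return [m for m in scored if score_key(m) <= threshold]
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    n_keep = max(1, int(np.ceil(percentile / 100.0 * len(scored)))) if scored else 0
    if percentile == 0:
        n_keep = min(1, len(scored))
    return scored[:n_keep]


def run_protocol(
    start_bundle: BundleState,
    ligand: LigandConformer | None,
    restraints_builder,
    stages: list[StageConfig],
    n_models: int,
    seed: int = 0,
    weights: SamplingWeights = SamplingWeights(),
    amplitudes=None,
    checkpoint_percentiles: tuple[float, float] = (15.0, 25.0),
    score_fn=None,
    logger=None,
) -> tuple[list[ModelRecord], dict]:
    """Full repacking pipeline: randomize -> stage 1 -> filter -> stages 2-3
    -> filter -> stage 4.

    ``restraints_builder(complex_state) -> RestraintSet`` maps restraints
    onto each fresh complex; ``score_fn(ModelRecord) -> float`` defaults to
    the packing+orientation score.  Returns surviving models and a funnel
    log ``{"stage1": n, "checkpoint1": n, "stage3": n, "checkpoint2": n,
    "stage4": n}``.
    """
    from .perturb import PerturbAmplitudes, place_ligand_random, randomize_bundle

    validate_stages(stages)
    if amplitudes is None:
        amplitudes = PerturbAmplitudes()
    if score_fn is None:
        from .scoring import default_model_score

        score_fn = default_model_score

    rng = np.random.default_rng(seed)
    funnel = {}
    models: list[ModelRecord] = []
    for m in range(n_models):
        s = int(rng.integers(0, 2**31 - 1))
        b = randomize_bundle(start_bundle, amplitudes, seed=s)
        lig = None
        if ligand is not None:
            lig = place_ligand_random(b, ligand, seed=s + 1, amplitudes=amplitudes)
        models.append(ModelRecord(model_id=m, seed=s, bundle=b, ligand=lig))

    def run_stage(pool, stage):
        out = []
        for rec in pool:
            cs = ComplexState(rec.bundle, rec.ligand)
            rset = restraints_builder(cs) if restraints_builder else RestraintSet()
            cs, trace = mc_optimize(cs, stage, weights, seed=rec.seed + stage.stage_id, restraints=rset)
            b, lig = cs.detach()
            energy = trace.energies[-1] if trace.energies else np.nan
            out.append(
                replace(rec, bundle=b, ligand=lig, energy=energy, stage_reached=stage.stage_id)
            )
        return out

    pool = models
    checkpoint = 0
    for stage in stages:
        pool = run_stage(pool, stage)
        funnel[f"stage{stage.stage_id}"] = len(pool)
        if logger:
            logger(f"stage {stage.stage_id}: {len(pool)} models")
        if stage.post_filter:
            for rec in pool:
                rec.energy = float(score_fn(rec))
            pct = checkpoint_percentiles[min(checkpoint, len(checkpoint_percentiles) - 1)]
            pool = select_by_threshold(pool, lambda m: m.energy, percentile=pct)
            checkpoint += 1
            funnel[f"checkpoint{checkpoint}"] = len(pool)
            if logger:
                logger(f"checkpoint {checkpoint}: {len(pool)} models survive")
            if not pool:
                import warnings

                warnings.warn(f"no models survived checkpoint {checkpoint}")
                return [], funnel
    return pool, funnel
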