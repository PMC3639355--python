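"""Stochastic expansion of conformational space: randomized rigid helix
displacement and randomized ligand placement.

Every operation takes an explicit seed and is bit-reproducible.  Helix
translations are strictly outward from the bundle center in the membrane
plane; tilt is about the helix center with a uniform tilt-plane azimuth;
spin is about the helix's own axis.  No internal geometry is ever altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bundle import BundleState
from .geometry import rotation_about_axis
from .ligands import LigandConformer


@dataclass(frozen=True)
class PerturbAmplitudes:
    max_translation: float = 5.0  # A, radially outward
    max_tilt: float = 20.0  # deg, about the helix center
    max_spin: float = 30.0  # deg, about the helix axis
    ligand_min_distance: float = 5.0  # A, ligand clearance from the bundle

    def __post_init__(self):
        vals = (self.max_translation, self.max_tilt, self.max_spin, self.ligand_min_distance)
        if any(v < 0 for v in vals):
            raise ValueError(f"amplitudes must be >= 0: {self}")


def draw_perturbation(rng: np.random.Generator, amplitudes: PerturbAmplitudes) -> dict:
    """Draw one helix perturbation (exposed separately so the distributions
    are directly testable)."""
    return {
        "translation": rng.uniform(0.0, amplitudes.max_translation),
        "tilt": rng.uniform(-amplitudes.max_tilt, amplitudes.max_tilt),
        "tilt_azimuth": rng.uniform(0.0, 360.0),
        "spin": rng.uniform(-amplitudes.max_spin, amplitudes.max_spin),
    }


def randomize_bundle(
    bundle: BundleState, amplitudes: PerturbAmplitudes, seed: int
) -> BundleState:
    """Independently displace every helix: outward translation U(0, t_max),
    tilt U(-tilt_max, +tilt_max) in a uniformly random plane, axial spin
    U(-spin_max, +spin_max)."""
    rng = np.random.default_rng(seed)
    new = bundle.copy()
    origin = bundle.bundle_center
    z = bundle.frame_axes[:, 2]
    for hid in range(1, bundle.n_helices + 1):
        draw = draw_perturbation(rng, amplitudes)
        sl = new.helix_slices[hid - 1]
        coords = new.structure.coords[sl]
        center = coords.mean(axis=0)
        seg = new.helix(hid)
        axis = seg.axis()
        # outward direction in the membrane plane
        radial = center - origin
        radial = radial - np.dot(radial, z) * z
        nr = np.linalg.norm(radial)
        if nr < 1e-9:
            radial = bundle.frame_axes[:, 0]
        else:
            radial = radial / nr
        if draw["tilt"] != 0.0:
            # tilt axis: perpendicular to the helix axis, uniform azimuth
            perp = np.cross(z, axis)
            if np.linalg.norm(perp) < 1e-9:
                perp = bundle.frame_axes[:, 0]
            perp = perp / np.linalg.norm(perp)
            tilt_axis = rotation_about_axis(axis, draw["tilt_azimuth"]) @ perp
            r = rotation_about_axis(tilt_axis, draw["tilt"])
            coords = (coords - center) @ r.T + center
        if draw["spin"] != 0.0:
            r = rotation_about_axis(axis, draw["spin"])
            coords = (coords - center) @ r.T + center
        if draw["translation"] != 0.0:
            coords = coords + draw["translation"] * radial
        new.structure.coords[sl] = coords
    return new


def place_ligand_random(
    bundle: BundleState,
    ligand: LigandConformer,
    seed: int,
    amplitudes: PerturbAmplitudes = PerturbAmplitudes(),
    max_attempts: int = 1000,
) -> LigandConformer:
    """Randomize ligand torsions and rigid placement, keeping every ligand
    heavy atom at least ``ligand_min_distance`` from every bundle heavy atom."""
    from scipy.spatial import cKDTree
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    heavy = bundle.structure.heavy_mask
    tree = cKDTree(bundle.structure.coords[heavy])
    center = bundle.bundle_center
    extent = float(np.max(np.linalg.norm(bundle.structure.coords[heavy] - center, axis=1)))
    min_d = amplitudes.ligand_min_distance

    for _ in range(max_attempts):
        pose = ligand.copy()
        for t in range(pose.n_rotatable):
            pose.rotate_torsion(t, rng.uniform(-180.0, 180.0))
        rot = Rotation.random(rng=rng).as_matrix()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(extent + min_d, extent + min_d + 10.0)
        pose.transform(rot, np.zeros(3))
        pose.coords = pose.coords - pose.coords[pose.heavy_mask].mean(axis=0)
        pose.coords = pose.coords + center + radius * direction
        d = tree.query(pose.coords[pose.heavy_mask], k=1)[0].min()
        if d >= min_d:
            return pose
    raise RuntimeError(
        f"could not place ligand >= {min_d} A from the bundle in {max_attempts} attempts"
    )
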