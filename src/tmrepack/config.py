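"""Target specifications and run configuration (YAML-backed).

A target spec names everything receptor-specific: helix spans, the
conserved-residue tether list per helix, the ligand/receptor anchor
restraints with their flat-bottom windows, the residues entering the ligand
score, pose-acceptance criteria and loop lengths.  Two example configs
ship with the package (a beta1AR-like and a D2-like setup).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml


@dataclass
class AnchorSpec:
    """Flat-bottom distance restraint between two atom-set centroids.

    ``receptor_atoms`` is a list of (residue number, atom name); the second
    side is either ``ligand_atoms`` (atom indices into the ligand) or
    ``receptor_atoms_b`` for receptor-internal windows.
    """

    receptor_atoms: list[tuple[int, str]]
    target: float
    half_width: float
    receptor_atoms_b: list[tuple[int, str]] = field(default_factory=list)
    ligand_atoms: list[int] = field(default_factory=list)
    k: float = 1.0

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("anchor half-width must be > 0")


@dataclass
class AcceptanceCriteria:
    """Pose-acceptance energy ceilings (all <= 0; values at the ceiling pass)."""

    hbond_asp_max: float = -0.2
    hbond_ser_max: float = -0.2
    aromatic_vdw_max: float = -0.3

    def __post_init__(self):
        if any(v > 0 for v in (self.hbond_asp_max, self.hbond_ser_max, self.aromatic_vdw_max)):
            raise ValueError("acceptance ceilings must be <= 0")


@dataclass
class TargetSpec:
    name: str
    helix_spans: list[tuple[int, int]]
    tether_residues: list[list[int]]
    serine_residues: list[int] = field(default_factory=list)
    aspartate_residue: int | None = None
    aromatic_residues: list[int] = field(default_factory=list)
    anchors: list[AnchorSpec] = field(default_factory=list)
    receptor_anchors: list[AnchorSpec] = field(default_factory=list)
    acceptance: AcceptanceCriteria = field(default_factory=AcceptanceCriteria)
    loop_lengths: list[int] = field(default_factory=list)
    ligand: str | None = None

    def validate(self, structure=None) -> None:
        if len(self.tether_residues) != len(self.helix_spans):
            raise ValueError("tether list must have one entry per helix")
        for i, (span, residues) in enumerate(zip(self.helix_spans, self.tether_residues)):
            for r in residues:
                if not (span[0] <= r <= span[1]):
                    raise ValueError(f"tether residue {r} outside helix {i + 1} span {span}")
        if structure is not None:
            for anchor in self.anchors + self.receptor_anchors:
                for rid, atom in anchor.receptor_atoms + anchor.receptor_atoms_b:
                    structure.atom_index(rid, atom)


def summarize_tethers(spec: TargetSpec) -> tuple[list[int], float]:
    """Per-helix tether counts and their arithmetic mean."""
    counts = [len(r) for r in spec.tether_residues]
    if sum(counts) == 0:
        import warnings

        warnings.warn("target spec has no tethers")
        return counts, 0.0
    return counts, float(np.mean(counts))


# ----------------------------------------------------------------- YAML I/O


def _anchor_from_dict(d: dict) -> AnchorSpec:
    return AnchorSpec(
        receptor_atoms=[tuple(x) for x in d.get("receptor_atoms", [])],
        receptor_atoms_b=[tuple(x) for x in d.get("receptor_atoms_b", [])],
        ligand_atoms=list(d.get("ligand_atoms", [])),
        target=float(d["target"]),
        half_width=float(d["half_width"]),
        k=float(d.get("k", 1.0)),
    )


def target_spec_from_dict(d: dict) -> TargetSpec:
    acc = AcceptanceCriteria(**d.get("acceptance", {}))
    return TargetSpec(
        name=d["name"],
        helix_spans=[tuple(s) for s in d["helix_spans"]],
        tether_residues=[list(r) for r in d["tether_residues"]],
        serine_residues=list(d.get("serine_residues", [])),
        aspartate_residue=d.get("aspartate_residue"),
        aromatic_residues=list(d.get("aromatic_residues", [])),
        anchors=[_anchor_from_dict(a) for a in d.get("anchors", [])],
        receptor_anchors=[_anchor_from_dict(a) for a in d.get("receptor_anchors", [])],
        acceptance=acc,
        loop_lengths=list(d.get("loop_lengths", [])),
        ligand=d.get("ligand"),
    )


def load_target_spec(path) -> TargetSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "helix_spans" not in data:
        raise ValueError(f"not a target spec file: {path}")
    return target_spec_from_dict(data)


def packaged_target_spec(name: str) -> TargetSpec:
    """Load one of the shipped example specs ('d2_like' or 'b1ar_like')."""
    ref = resources.files("tmrepack.configs") / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return load_target_spec(path)


def spread_tethers(spans: list[tuple[int, int]], counts: list[int]) -> list[list[int]]:
    """Deterministically pick ``counts[i]`` evenly spaced residues in each
    span (the identities of conserved residues are a modeling input; only
    the per-helix counts are prescribed)."""
    out = []
    for (first, last), n in zip(spans, counts):
        if n == 0:
            out.append([])
            continue
        idx = np.unique(np.round(np.linspace(first, last, n)).astype(int))
        out.append([int(i) for i in idx])
    return out
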