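# tmrepack

Ligand-biased repacking of transmembrane (7TM) helix bundles in
internal-coordinate space.

Starting from the helical segments of a template model, `tmrepack`:

1. represents each helix by six rigid-body variables (radial position,
   azimuth, axial offset, tilt, tilt azimuth, spin) layered over the
   full-atom coordinates (`tmrepack.bundle`);
2. expands conformational space by randomized helix displacement —
   0–5 Å outward, ±20° tilt, ±30° spin — and randomized ligand placement
   at ≥ 5 Å clearance (`tmrepack.perturb`);
3. re-compacts each copy by four-stage Metropolis Monte Carlo with
   stepwise release of degrees of freedom, soft-core-to-hard van der Waals
   ramping, conserved-residue Cα tethers that are softened and switched
   off, flat-bottom ligand anchor restraints, and biased move sampling
   (ligand : pocket : helix : rest = 100 : 50 : 20 : 2)
   (`tmrepack.mc`, `tmrepack.energy`);
4. scores models with packing terms (volume, area, buried pockets,
   helix-center distances), orientation terms (hydrophilic exposure of the
   membrane mid-third, >50° tilt, elevation, loop-span feasibility, anchor
   windows) and target-specific ligand terms, filtering the pool at two
   checkpoints (`tmrepack.scoring`);
5. ranks surviving receptor models by docking a compound library against
   grid maps and counting unique agonists whose poses pass the
   key-interaction criteria (amine–aspartate hydrogen bond ≤ −0.2,
   serine hydrogen bond ≤ −0.2, aromatic vdW ≤ −0.3 kcal/mol), plus RMSD
   analytics, binding-site box transfer and atom-property-field summaries
   (`tmrepack.selection`).

Everything is testable offline: `tmrepack.fixtures` generates ideal
helix bundles, graded decoy sets, a binding-pocket bundle and small-molecule
ligands (from packaged SMILES) deterministically.

The energy model is a documented surrogate (generic Lennard-Jones tables,
ε(r) = 4r electrostatics, a geometric hydrogen-bond well, Gasteiger ligand
charges); all energy thresholds are configuration defaults.

## CLI

```bash
tmrepack fixtures --kind bundle --out-dir out/      # ideal 7TM fixture (PDB)
tmrepack fixtures --kind ligand --name R-NPA        # ligand fixture (SDF)
tmrepack score out/ideal_bundle.pdb                 # packing/orientation report
tmrepack tethers --config d2_like                   # per-helix tether counts + mean
tmrepack repack --config d2_like --seed 1 --n-models 10 \
    --stage-budgets 400,400,600,800 --out-dir run/  # staged pipeline on the fixture
tmrepack dock-filter --ligand toy_catechol_amine    # dock + pose filters
tmrepack rmsd ref.pdb model.pdb --fit ca            # superposition RMSD
tmrepack apf --ligand toy_catechol_amine            # atom property fields (DX)
```

Two target configurations ship with the package (`d2_like`, `b1ar_like`);
`--config` also accepts a path to your own YAML (helix spans, tether lists,
anchor windows, score-term residues, acceptance criteria, loop lengths).
Every run writes a `run_log.json` with the config hash, seed and version.

## Layout

```
src/tmrepack/
  bundle.py       helix segments, rigid-body variables, bundle axis/frame
  perturb.py      randomized helix/ligand perturbation
  energy.py       surrogate force field, tethers, flat-bottom anchors
  forcefield.py   parameter tables (LJ, radii, charges, reference areas)
  mc.py           staged Monte Carlo, move sampling, checkpoints, pipeline
  scoring.py      packing / orientation / ligand scores
  selection.py    grid-map docking, pose filters, ranking, RMSD, APF
  fixtures.py     deterministic synthetic structures and ligands
  config.py       target specifications (YAML)
  cli.py          command-line interface
  configs/        shipped d2_like / b1ar_like target specs
```
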