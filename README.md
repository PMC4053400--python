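# siescan

Post-simulation analysis toolkit for protein–ligand complexes: endpoint
(SIE) binding free-energy rescoring, trajectory dynamics analysis,
per-residue polar/hydrogen-bond energetics, hydrophobic-contact profiling,
and computational alanine scanning — all runnable on synthetic toy systems
generated by the package itself.

## What it does

* **`siescan.structure_io`** — single-model PDB structures, multi-model PDB
  trajectories, and a TSV per-atom parameter table (partial charges,
  Lennard-Jones parameters, vdW radii) combined into an annotated
  `MolecularSystem` with `protein`/`ligand` selections.
* **`siescan.dynamics`** — Kabsch superposition, per-frame RMSD, per-residue
  RMSF about the iterated mean structure, the dynamic cross-correlation
  matrix (DCCM) over C-alpha atoms, and named-region summaries /
  bound-vs-unbound difference tables.
* **`siescan.energetics`** — the solvated interaction energy terms:
  intermolecular Coulomb and 12-6 Lennard-Jones energies, Shrake–Rupley
  surface-area change on binding, and a reaction-field change from a
  finite-difference two-dielectric Poisson solver; combined as
  `dG = alpha*(E_c + E_vdw + dG_R + gamma*dMSA) + C` with the standard
  published calibration (alpha 0.1048, D_in 2.25, radius scale 1.1,
  gamma 0.0129 kcal/mol/A^2, C −2.89 kcal/mol). Snapshot statistics are
  mean ± standard error; `ic50_to_dg` converts assay IC50 values.
* **`siescan.hbond`** — geometric hydrogen-bond detection with trajectory
  occupancies, H…acceptor distance distributions, the calibrated 12-10
  empirical H-bond energy (parameters 5.571 / 668.580), per-residue
  screened-Coulomb polar energies with the sigmoidal distance-dependent
  dielectric (AutoDock-3 style, overall scale 1.558), and LIGPLOT-style
  hydrophobic contacts (C/S pairs within 3.9 A).
* **`siescan.alanine`** — X→ALA mutants by truncation at C-gamma (new HB1
  hydrogen on the old CB→CG axis at 1.09 A), re-parameterization, and
  component-wise ddG reports with consistency flags.
* **`siescan.synth`** — a deterministic toy complex (helical peptide with
  ARG/TYR/LEU probes + carboxylate ligand, net charge −1) and trajectory
  generators with planted correlation blocks and H-bond distance peaks.
* **`siescan.report` / `siescan.cli`** — component-table ingestion
  (`mean±err` cells), pairwise signed comparison tables, ddG tables, and a
  multi-stage pipeline driver.

Bundled under `siescan/data/` are the published SIE component, H-bond and
polar-interaction tables for the three A-FABP inhibitor complexes
(8CA/F8A/I4A, wild type and R126A), used as fixed inputs by the report
arithmetic and the acceptance script.

## CLI

```sh
siescan simulate --seed 1 --n-frames 100 --out sim/
siescan dccm  --structure sim/structure.pdb --trajectory sim/trajectory.pdb \
              --parameters sim/parameters.tsv --out out/
siescan sie   --structure sim/structure.pdb --trajectory sim/trajectory.pdb \
              --parameters sim/parameters.tsv --out out/
siescan alascan --residue A:4 --structure sim/structure.pdb \
              --trajectory sim/trajectory.pdb --parameters sim/parameters.tsv \
              --out out/
siescan report --components src/siescan/data/afabp_sie_components.tsv --out rep/
siescan pipeline config.yml --out out/
```

A pipeline config is a plain `key: value` file, e.g.

```yaml
stages: [simulate, dccm, rmsf, sie, hbonds, polar, contacts]
seed: 1
n_frames: 100
regions:
  R1: "2-4"
```

## Notes and approximations

* The reaction-field solver is a finite-difference Poisson solver
  (fraction-smoothed dielectric boundary, analytic Dirichlet boundary,
  uniform-dielectric reference solve for self-energy cancellation),
  validated against the Born-ion closed form (<3% over a radius sweep) and
  by grid self-convergence — not against a boundary-element reference.
* Mutant energies are rescored on truncated wild-type snapshots by default;
  running fresh mutant dynamics is out of scope.
* Structures without hydrogens are read fine, but hydrogen-bond analysis
  refuses to run on them (no protonation assignment is performed).
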