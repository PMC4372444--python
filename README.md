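# memnmr

Ensemble analysis of membrane-associated peptides from sparse solid-state NMR
chemical shifts. The package implements the full analysis chain for a
28-residue lipidated peptide bound to lipid vesicles:

- **`memnmr.shift_data`** — chemical-shift table I/O, restraint selection
  (e.g. the 55 CO/Cα/Cβ/Hα restraints of the shipped experimental table),
  and the Cα−Cβ secondary-shift index against a packaged Wishart-style
  random-coil reference.
- **`memnmr.conformers`** — conformer pools: ideal-geometry backbone
  construction from φ/ψ/ω torsions (NeRF), multi-model PDB + sidecar I/O,
  and the three pool filters (membrane-depth slab on the anchor-residue Cα,
  receptor clearance, lowest-energy percentile).
- **`memnmr.ensemble_selection`** — Monte Carlo selection of a 10–30-model
  ensemble whose ensemble-average predicted shifts minimize the pooled RMSD
  to experiment, with carbon shifts scaled down by 4. Greedy acceptance by
  default; fixed-temperature Metropolis optional. Verified against exhaustive
  enumeration on small pools.
- **`memnmr.secstruct`** — polyproline-II overlay on DSSP-style strings
  (φ = −75 ± 29°, ψ = 145 ± 29°, two sequential residues required),
  per-position ensemble composition, Ramachandran export, a classic `.dssp`
  reader and a torsion-only fallback assigner.
- **`memnmr.nmr_dynamics`** — 1D lattice spin-diffusion model (clamped
  reservoir or initial pulse), T1 correction and 900-ms normalization of
  buildup curves, step-distance fitting, and C–H order parameters
  (rigid limit 22.8 kHz).
- **`memnmr.membrane_binding`** — %bound from supernatant/pellet
  fluorescence, the 0.45 effective-lipid correction, hyperbolic isotherm
  fitting (K_D, Bmax), ΔG° on the mole-fraction standard state
  ([W] = 55.5 M), a simple partition model, Henderson–Hasselbalch net
  charge, and binding-energy summation.
- **`memnmr.synthetic_data`** — seeded generators replacing the external
  folding/shift-prediction tools: mixed helix/PPII/coil conformer pools with
  a linear toy shift predictor, ground-truth shift tables, binding datasets
  and buildup curves, so every stage is testable offline.
- **`memnmr.pipeline_cli`** — orchestration (filter → select → secondary
  structure) from a YAML config, JSON run reports, and the `memnmr` CLI.

## CLI

```sh
memnmr shifts csi --table table.csv                    # chemical-shift index
memnmr binding charge --sequence GSSFLSPEHQRVQQRKESKKPPAKLQPR --ph 6
memnmr binding fit --data assay.csv                    # K_D, Bmax, dG0
memnmr spindiff simulate --sites 10 --omega 25
memnmr spindiff fit --curve ser3.csv --omega 25 --nmax 12
memnmr simulate pool --n-models 1000 --seed 7 --out pool_dir/
memnmr filter --pool pool.pdb --energies energies.tsv --receptor receptor.pdb
memnmr select --pool pool.pdb --pred-shifts pred.csv --exp-shifts exp.csv --seed 17
memnmr run --config run.yaml                           # full pipeline
```

`memnmr run` exit codes: 0 success, 2 config error, 3 stage failure.

## File formats

- Shift CSV: `residue_number,residue_name,atom,shift_ppm,uncertainty_ppm`
  (atoms CO/CA/CB/CG/CD/HA/HB/HG/HD; uncertainty optional).
- Pools: multi-model PDB (backbone N/CA/C) + `model_id,energy` TSV +
  per-model predicted-shift CSV.
- Buildup CSV: `mixing_time_ms,intensity`; binding CSV:
  `lipid_total_mM,I_supernatant,I_pellet,replicate`.
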