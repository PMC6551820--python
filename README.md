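# memmatch

Quantitative analysis of hydrophobic mismatch in transmembrane (TM) helix
dimers: dimer orientation metrics, alpha-helicity assignment, gridded
membrane-thickness and perturbation maps, the hydrophobic-length/mismatch
calculus, and dimerization-assay statistics — validated against synthetic
dimer/bilayer ensembles with known ground truth.

## What's inside

| Module | Purpose |
| --- | --- |
| `memmatch.structure` | Domain types (`Atom`, `Frame`, `Trajectory`, `DimerTopology`), multi-model PDB and GRO readers/writers (internal unit: Angstrom), atom selections |
| `memmatch.geometry` | Dimer tilt angle, crossing angle, weighted Kabsch superposition, per-frame RMSD, per-residue RMSF |
| `memmatch.helicity` | Amide-hydrogen placement, electrostatic backbone H-bond energies, alpha-helix assignment (two-consecutive-turn rule), per-chain helicity series |
| `memmatch.membrane` | Leaflet split, lateral thickness maps (default 3.3 A grid), far-field bulk thickness, hydrophobic length (1.5 A/residue) and mismatch sign rule |
| `memmatch.synthetic` | Ground-truth generators: ideal helices (exact 1.5 A rise, 100 deg twist), helical dimers at configurable tilt/crossing inside planar marker bilayers with Gaussian dents and thermal noise; plate-style assay tables |
| `memmatch.assay` | Normalization (OD600/luciferase), relative fluorescence, merged-homodimer fold change, Student's t tests, Benjamini-Hochberg q-values, dimer/reduced/background calls |

## CLI

All commands are under a single `memmatch` entry point:

```bash
# generate a synthetic dimer/bilayer trajectory with known ground truth
memmatch simulate --config cfg.json --out traj.pdb --truth truth.json

# per-frame tilt and crossing angle
memmatch tilt --traj traj.pdb --discard-fraction 0.5 --out tilt.csv

# per-frame per-chain alpha-helical fraction
memmatch helicity --traj traj.pdb --out helicity.csv

# thickness map + bulk estimate (CSV map + JSON sidecar)
memmatch thickness --traj traj.pdb --marker "name P" --spacing 3.3 \
    --far-fraction 0.25 --out map.csv

# assay statistics from a long-format plate table
memmatch assay --table plate.csv --positive GpA:GpA --negative H2:H2 \
    --alpha 0.05 --out results.csv
```

`simulate` config keys mirror `memmatch.synthetic.SyntheticConfig`
(sequences, tilt_deg, crossing_deg, bulk_pp_thickness,
bulk_hydrophobic_thickness, lipids_per_leaflet, dent_amplitude, dent_sigma,
noise_sigma, n_frames, seed). The assay table needs columns
`construct_n, construct_c, replicate, batch, raw_fluorescence, normalizer`.

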