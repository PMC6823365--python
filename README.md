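# groovekit

Analysis toolkit for the lipid-translocation groove of TMEM16-family
scramblases: trajectory feature extraction and tICA conformational
landscapes, groove hydration and lipid-penetration metrics, sphere-probe
pore-radius profiling, membrane-slab linearized Poisson–Boltzmann (LPBE)
electrostatics, and kinetic modelling of the dithionite scrambling and
chloride-flux assays.  A synthetic-data module generates fixtures with the
statistical/geometric structure every stage assumes, so the whole pipeline
is testable without MD trajectories or deposited structures.

## Modules

| module | what it does |
| --- | --- |
| `groovekit.model_io` | PDB/PQR read–write, atom selection, Kabsch superposition, region RMSD |
| `groovekit.synthetic` | two-state feature series, toy groove structures, ring-built pore geometries, point-charge systems, simulated fluorescence traces |
| `groovekit.features` | the five groove feature distances, occlusion/contact labels, water counts (3 Å rule, vestibule slab), lipid head/tail penetration (5 Å rule) |
| `groovekit.tica` | time-lagged independent component analysis, projections, k-means microstates, density landscapes |
| `groovekit.pore` | slice-wise maximal-sphere pore-radius profiles, pore minima, pore-region point sets |
| `groovekit.electrostatics` | finite-difference LPBE with protein/membrane-slab dielectric model, EP profiles along the pore axis, OpenDX export |
| `groovekit.kinetics` | closed-form scrambling fluorescence model with eigenstructure, trace simulation, multi-start fitting, leak and flux quantification |
| `groovekit.cli` | `groovekit` command-line pipelines with config, manifests and QC reports |

## CLI

```sh
groovekit features traj.pdb --out run1          # features -> tICA -> microstates
groovekit pore structure.pdb --with-ep --out r2 # pore profile (+ LPBE EP profile)
groovekit rmsd a.pdb b.pdb --region groove      # backbone RMSD over TM3-TM6
groovekit scramble-sim --f0 0.3 --alpha 0.01 --beta 0.005 --gamma 2 --out sim
groovekit scramble-fit sim/trace.csv --out fits
groovekit leak-fit pf_trace.csv
groovekit flux --delta-cl 0.3 --delta-cl-pf 1.2
groovekit synth two-state --n-frames 10000 --out fixtures
```

All numeric conventions (cutoffs, dielectric constants, lag time, helix
ranges, …) live in a single YAML run config; defaults are materialized into
`manifest.json` next to every output.  Exit codes: 0 success, 2 config
error, 3 data error, 4 numerical failure.

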