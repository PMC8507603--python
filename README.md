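# membind

Tools for quantifying how peripheral membrane-binding protein domains
associate with lipid bilayers, exercised end to end on a built-in
rigid-body Brownian-dynamics membrane simulator with analytically known
energetics.

The package covers the full analysis protocol used in simulation studies
of peripheral domain/bilayer recognition:

| stage | module | what it does |
| --- | --- | --- |
| synthetic data | `membind.toysim` | charged multi-bead rigid body over a planar PC/PS/PIP2 bilayer (explicit diffusing head groups or a mean-field charged plane with closed-form energetics); umbrella-window and alchemical lambda-window sample generators; analytic free-energy oracle |
| encounter kinetics | `membind.kinetics` | minimum protein-lipid distance traces, hysteresis event segmentation, ensemble averaging, exponential decay fits |
| binding modes | `membind.orientation` | R_zz orientation statistic (zz element of the least-squares rotation vs a reference), distance/R_zz density maps, grid mode detection, re-referencing to a primary mode, probable/physical/productive scoring, retained/rotated/unbound classification |
| potentials of mean force | `membind.wham` | from-scratch WHAM (Newton-accelerated, self-consistency certified), bootstrap errors, well depths, well-depth differences |
| alchemical free energies | `membind.fep` | Bennett acceptance ratio and a self-consistent multistate estimator, bound-minus-free differencing of PIP2-to-PC head-group discharge, counterion bookkeeping, FEP-vs-dPMF consistency check |
| lipid statistics | `membind.contacts` | per-group/per-species contact frequencies, basic-bead/phosphate contact counts, radial lipid enrichment and clustering contrasts |
| orchestration | `membind.pipeline`, `membind.cli` | one-config protocol runner with seed management and a JSON report |

Units throughout: nm, ps, kJ/mol, K, elementary charges; k_B = 0.0083145 kJ/mol/K.
Head-group charges default to PC 0, PS -1, PIP2 -5.

## Command line

`membind` exposes one subcommand per stage:

```sh
membind simulate --config sim.yaml --out trajs/ --membrane PC:PS:PIP2 --repeats 25 --seed-base 1
membind kinetics --traj-glob 'trajs/*.h5' --on-cutoff 0.5
membind modes    --traj-glob 'trajs/*.h5' --reference auto --out modes.json --map map.npz
membind wham     --windows windows.tsv --temp 323 --out pmf.csv
membind fep      --bound bound.npz --free free.npz --out fep.json
membind contacts --traj trajs/traj_PC-PS-PIP2_0.h5 --cutoff 0.5 --out contacts.csv
membind protocol --config protocol.yaml --out run1/
```

`membind protocol` runs everything (ensemble simulation, kinetics, mode
maps, umbrella/WHAM, per-lipid FEP with counterion bookkeeping, contact
statistics, and the FEP-vs-dPMF consistency report) from a single YAML
config and writes `report.json` plus all intermediates. Reports are
deterministic for a fixed config and base seed.

Trajectories are stored in an HDF5 container
(`/frames/{time,com,quaternion,lipid_xy}`, `/body`, `/meta`); density
maps and lambda-window sets as `.npz`. Round-trips are lossless.

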