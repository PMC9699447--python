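# hnpmd

Off-lattice coarse-grained **H/N/P bead-spring protein model**: a molecular
dynamics simulator plus a structural-analysis pipeline for single chains
built from periodic hydrophobic (H) / neutral (N) / hydrophilic (P) repeat
units such as `H3N1P1`.

Each bead is one residue (a Cα position). The force field combines stiff
harmonic bond stretching, harmonic bending of the bond-vector deflection
angle, a threefold torsion with degenerate trans/gauche minima, and a
truncated-and-shifted 12-6 Lennard-Jones potential between beads at least
four residues apart, with a class-pair interaction matrix in which only H-H
contacts attract. Chains are advanced with velocity-Verlet dynamics under a
Nosé-Hoover chain thermostat and analyzed for:

- per-bond stretch/bend/torsion/nonbonded energies,
- radius of gyration and its gyration-tensor principal components,
- the bond orientational order parameter P along the chain's long axis,
- trans/gauche dihedral states, stem (consecutive-trans run) length
  distributions, and
- residue contact counts (pairs within 0.65 nm, sequence separation > 3),

swept across reduced temperatures T* = kB·T/εh (typically 0.3-1.5).

## Quick start (Python)

```python
from hnpmd import (ForceField, RunProtocol, build_sequence, run_quench,
                   sweep_summary)

ff = ForceField()                            # all model defaults
seq = build_sequence("H3N1P1", 120)          # tile the repeat unit
proto = RunProtocol(schedule=((1.5, 20_000), (0.6, 100_000)), seed=7,
                    snapshot_stride=1_000)
traj = run_quench(seq, ff, proto)            # random coil -> quench
table, stems = sweep_summary({0.6: traj.at_tstar(0.6)})
print(table[["tstar", "rg_mean", "order_parameter_mean", "contacts_mean"]])
```

## CLI

```sh
hnpmd build --unit H3N1P1 --length 240 --seed 7 --out chain.xyz
hnpmd run --config run.yaml            # one quench protocol
hnpmd analyze --traj run.xyz --meta run.yaml --out summary.csv --stems stems.csv
hnpmd experiment --config experiment.yaml [--dry-run] [--resume]
```

`hnpmd experiment` runs the full factorial (repeat unit × chain length ×
T* × seed) from one YAML config, writing per-run XYZ trajectories + YAML
sidecars, a merged long-format `results.csv`, per-temperature stem
histograms and a `manifest.json` with the config hash and per-run seeds;
re-invoking with `--resume` skips completed runs. See
`examples/experiment.yaml`.

Conventions worth knowing:

- dihedral angles are measured from the trans state (phi = 0 ⇔ trans; trans
  iff |phi| ≤ π/3); stems are maximal runs of ≥ 4 consecutive trans
  dihedrals and stem length is counted in dihedral units (an all-trans chain
  of N beads has one stem of length N-3);
- coordinates are nm, energies kcal/mol, time ps; trajectories are plain
  multi-frame XYZ whose comment lines carry time, thermostat target and
  energy terms.

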