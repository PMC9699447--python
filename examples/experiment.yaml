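# Desk-scale example: two repeat units, one length, two temperatures, two seeds.
# Paper-scale values (lengths up to 300, steps_per_leg ~1e7, T* grid 0.3-1.5)
# are reachable by editing the same fields.
units: [H3N1P1, H4N1P1]
lengths: [50]
tstar_grid: [0.4, 1.2]
seeds: [1, 2]
steps_per_leg: 100000
init_tstar: 1.5
init_steps: 20000
equilibration_fraction: 0.5
snapshot_stride: 500
dt_fs: 2.5
tau_fs: 25.0
mass: 110.0
output_dir: experiment_out
forcefield: {}
ramp: false
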