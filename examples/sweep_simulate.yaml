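# Sweep specification: reduced simulation map over transmission mode and
# bottleneck size (the branching map at desk scale). Each cell runs
# `replicates` seeds; per-cell seeds derive from base_seed and the cell
# and replicate indices, so the sweep is reproducible end to end.
mode: simulate

axes:
  lam: [0.0, 0.25, 0.5, 0.75, 1.0]
  k: [1, 2, 4, 8]

replicates: 3
base_seed: 1

# Forwarded to SimConfig; sweep cells default to shortened runs
# (500 hosts, 2000 generations) relative to single-run defaults.
sim_overrides:
  n_hosts: 500
  n_generations: 2000
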