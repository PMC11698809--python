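nx: 20
ny: 20
voxel_size: 30.0
n_initial_cells: 40
seeding_radius: 70.0
dt_diffusion: 1.0
dt_mechanics: 1.0
snapshot_interval: 180.0
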