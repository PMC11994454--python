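kind: beads
shape:
- 9
- 45
- 45
voxel_xy_um: 0.529101
z_um:
- -2.0
- -1.5
- -1.0
- -0.5
- 0.0
- 0.5
- 1.0
- 1.5
- 2.0
bead_radius_um: 0.25
bead_density_per_um3: 0.001
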