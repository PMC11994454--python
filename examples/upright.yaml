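na: 1.05
mag_objective: 25.0
mag_relay: 1.64
wavelength_nm: 525.0
refr_index: 1.33
mla_pitch_um: 136.5
mla_focal_um: 2800.0
pixel_size_um: 6.5
n_views: 21
mag_relay_mla_to_sensor: 1.0
scan:
  s: 3
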