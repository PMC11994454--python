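na: 1.4
mag_objective: 63.0
mag_relay: 1.0
wavelength_nm: 525.0
refr_index: 1.518
mla_pitch_um: 100.0
mla_focal_um: 2100.0
pixel_size_um: 6.5
n_views: 13
mag_relay_mla_to_sensor: 0.845
scan:
  s: 3
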