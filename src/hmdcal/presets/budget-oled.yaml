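# Mid-range OLED with slight top-end clipping in selective mode.
# Fictional device illustrating one measurement regime.
name: budget-oled
primaries:
  R: {peak_Y: 22.5, spd: [{center_nm: 618.0, width_nm: 10.0}]}
  G: {peak_Y: 61.0, spd: [{center_nm: 522.0, width_nm: 12.0}]}
  B: {peak_Y: 7.1,  spd: [{center_nm: 458.0, width_nm: 9.0}]}
gamma_native: 2.2
clip_caps: {R: 1.0, G: 0.95, B: 1.0}
seed: 0
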