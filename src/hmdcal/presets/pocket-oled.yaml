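# Dim compact OLED: low peak luminance across the board.
# Fictional device illustrating one measurement regime.
name: pocket-oled
primaries:
  R: {peak_Y: 4.2, spd: [{center_nm: 621.0, width_nm: 10.0}]}
  G: {peak_Y: 11.8, spd: [{center_nm: 531.0, width_nm: 12.0}]}
  B: {peak_Y: 1.9, spd: [{center_nm: 459.0, width_nm: 9.0}]}
gamma_native: 2.3
seed: 0
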