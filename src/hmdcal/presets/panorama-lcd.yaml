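# Bright wide-field LED-backlit LCD: broader primaries than OLED.
# Fictional device illustrating one measurement regime.
name: panorama-lcd
primaries:
  R: {peak_Y: 15.2, spd: [{center_nm: 611.0, width_nm: 16.0}]}
  G: {peak_Y: 38.5, spd: [{center_nm: 541.0, width_nm: 18.0}]}
  B: {peak_Y: 5.6,  spd: [{center_nm: 451.0, width_nm: 14.0}]}
gamma_native: 2.1
seed: 0
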