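# Bright AMOLED panel: narrow primaries, green-dominant luminance.
# Fictional device illustrating one measurement regime; not a claim about
# any real headset.
name: aurora-amoled
primaries:
  R: {peak_Y: 18.0, spd: [{center_nm: 612.0, width_nm: 9.0}]}
  G: {peak_Y: 46.0, spd: [{center_nm: 524.0, width_nm: 11.0}]}
  B: {peak_Y: 6.5,  spd: [{center_nm: 452.0, width_nm: 8.0}]}
gamma_native: 2.2
seed: 0
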