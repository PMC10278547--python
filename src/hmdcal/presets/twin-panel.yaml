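# Dual-panel device (uOLED center + LCD periphery): bimodal primaries with
# distinct lobes from the two panel technologies.
# Fictional device illustrating one measurement regime.
name: twin-panel
primaries:
  R:
    peak_Y: 34.0
    spd:
      - {center_nm: 629.0, width_nm: 9.0, amplitude: 1.0}
      - {center_nm: 609.0, width_nm: 14.0, amplitude: 0.45}
  G:
    peak_Y: 88.0
    spd:
      - {center_nm: 539.0, width_nm: 11.0, amplitude: 1.0}
      - {center_nm: 521.0, width_nm: 16.0, amplitude: 0.4}
  B:
    peak_Y: 11.0
    spd:
      - {center_nm: 449.0, width_nm: 8.0, amplitude: 1.0}
      - {center_nm: 462.0, width_nm: 13.0, amplitude: 0.35}
gamma_native: 2.2
seed: 0
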