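# Hexagonal thermolysin: exchange ~2 M ammonium sulfate to pure water over
# 15 min (thermolysin is nearly insoluble at low salt, so crystals survive
# deionized water). Target is the empty solution.
schema_version: 1
label: thermolysin 2 M AS -> water / 15 min
start:
  label: high-salt mother liquor
  components:
    - {name: ammonium sulfate, concentration: 2, unit: M, density_contribution: 0.06}
target:
  label: water
  components: []
pot:
  volume_ul: 40
  evaporation_ul_per_h: 0
gradient:
  final_fraction: 0.95
  duration_min: 15
  mode: linear
pump:
  syringe_volume_ml: 1
  label: BD 1 ml
outputs:
  sample_dt_min: 0.25
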