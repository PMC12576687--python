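# Orthorhombic bovine alpha-lactalbumin: introduce 25% v/v glycerol
# cryoprotectant over 50 min while keeping the PEG/phosphate background.
# Glycerol-rich inflow is denser than the pot solution: offset the crystal
# from the inflow tube (see the density note in the run report).
schema_version: 1
label: alpha-lactalbumin 0->25% glycerol / 50 min
start:
  label: well solution
  components:
    - {name: PEG 8000, concentration: 20, unit: "%w/v"}
    - {name: KH2PO4, concentration: 50, unit: mM}
target:
  label: cryo target
  components:
    - {name: PEG 8000, concentration: 20, unit: "%w/v"}
    - {name: KH2PO4, concentration: 50, unit: mM}
    - {name: glycerol, concentration: 25, unit: "%v/v", density_contribution: 0.0025}
pot:
  volume_ul: 40
  evaporation_ul_per_h: 0
gradient:
  final_fraction: 0.95
  duration_min: 50
  mode: linear
pump:
  syringe_volume_ml: 1
  label: BD 1 ml
outputs:
  sample_dt_min: 0.5
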