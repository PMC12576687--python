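# Tetragonal hen egg-white lysozyme: soften hypotonic shock by lowering NaCl
# gradually from the growth condition (8% w/v) to 3% w/v over 40 min.
# The target carries 5 mg/ml lysozyme to suppress surface dissolution.
# Evaporation: 0 here (short run); an open pot loses ~6 µl/h, a covered one ~1 µl/h.
schema_version: 1
label: lysozyme 8->3% NaCl / 40 min
start:
  label: well solution
  components:
    - {name: NaCl, concentration: 8, unit: "%w/v"}
    - {name: sodium acetate, concentration: 20, unit: mM}
target:
  label: low-salt target
  components:
    - {name: NaCl, concentration: 3, unit: "%w/v"}
    - {name: sodium acetate, concentration: 20, unit: mM}
    - {name: lysozyme, concentration: 5, unit: mg/ml}
pot:
  volume_ul: 40
  evaporation_ul_per_h: 0
gradient:
  final_fraction: 0.95
  duration_min: 40
  mode: linear
pump:
  syringe_volume_ml: 1
  label: BD 1 ml
outputs:
  sample_dt_min: 0.5
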