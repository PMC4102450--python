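# Nsg1-GFP on the ONM of an early-anaphase nucleus with the fitted 300 nm
# single-ring lipid domain at the neck (P_in = 3.5%).
geometry:
  stage: EA
  mother: {semi_axis_long: 1.2, semi_axis_short: 0.9}
  daughter: {semi_axis_long: 0.95, semi_axis_short: 0.8}
species:
  name: Nsg1
  enclosure: ONM
  D_eff: 0.3
  D_in_domain: 0.1
  copy_number: 250
barriers:
  - {kind: preset, name: ea_single_ring_nsg1}
protocol:
  t_total: 60.0
  sampling_dt: 0.5
dt: 0.001
seed: 1
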