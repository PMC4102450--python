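# GFP-Src1 on the INM of a reduced-scale late-anaphase nucleus, with the
# fitted homogeneous bridge domain (P_in = 35%) and the bleach spot at 20%
# of the bridge length.  Run with:
#   mitoflip simulate examples/la_homogeneous_src1.yaml -o trace.csv
geometry:
  stage: LA
  mother: {piriform_scale: 1.4, piriform_deviation: 0.5}
  daughter: {piriform_scale: 1.2, piriform_deviation: 0.5}
  bridge_length: 2.0
  bridge_diameter: 0.3
species:
  name: Src1
  enclosure: INM
  D_eff: 0.3
  D_in_domain: 0.1
  copy_number: 200
barriers:
  - {kind: lipid_domain, layout: homogeneous_bridge, surfaces: INM, P_in: 35.0}
protocol:
  placement: bridge_fraction
  bridge_fraction: 0.2
  t_total: 150.0
  sampling_dt: 1.0
dt: 0.001
seed: 3
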