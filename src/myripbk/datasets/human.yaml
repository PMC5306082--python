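# Human parameter set for the myristicin PBK model.
# The slowly perfused flow fraction is the remainder of cardiac output
# after liver, fat and rapidly perfused tissue (100 - 22.7 - 5.2 - 47.3).
species: human
molecular_weight: {value: 192.21, unit: g/mol}
absorption_rate_constant: {value: 1.0, unit: 1/h}
body_weight: {value: 60.0, unit: kg}
cardiac_output: {value: 310.0, unit: L/h}
tissue_volume_fractions:
  liver: {value: 2.6, unit: percent}
  fat: {value: 21.4, unit: percent}
  rapidly_perfused: {value: 5.0, unit: percent}
  slowly_perfused: {value: 51.7, unit: percent}
  blood: {value: 7.9, unit: percent}
flow_fractions:
  liver: {value: 22.7, unit: percent}
  fat: {value: 5.2, unit: percent}
  rapidly_perfused: {value: 47.3, unit: percent}
  slowly_perfused: remainder
partition_coefficients:
  parent:
    liver: 6.63
    fat: 105.78
    rapidly_perfused: 6.63
    slowly_perfused: 4.18
  metabolite_liver: 1.64
protein_yields:
  microsomal: {value: 32.0, unit: mg/g}
  s9: {value: 143.0, unit: mg/g}
clogp:
  parent: 3.1721
  metabolite: 1.6151
kinetics_invitro:
  DHM:
    kind: michaelis_menten
    vmax: {value: 0.08, sd: 0.01, unit: nmol/min/mg}
    km: {value: 33.0, sd: 12.0, unit: uM}
    protein_basis: microsomal
  3HM:
    kind: michaelis_menten
    vmax: {value: 0.29, sd: 0.14, unit: nmol/min/mg}
    km: {value: 1629.0, sd: 1545.0, unit: uM}
    protein_basis: microsomal
  HM:
    kind: michaelis_menten
    vmax: {value: 0.17, sd: 0.03, unit: nmol/min/mg}
    km: {value: 234.0, sd: 132.0, unit: uM}
    protein_basis: microsomal
  DHA:
    kind: michaelis_menten
    vmax: {value: 0.93, sd: 0.13, unit: nmol/min/mg}
    km: {value: 118.0, sd: 36.0, unit: uM}
    protein_basis: microsomal
  HMG:
    kind: michaelis_menten
    vmax: {value: 0.08, sd: 0.03, unit: nmol/min/mg}
    km: {value: 3140.0, sd: 2434.0, unit: uM}
    protein_basis: s9
  HMO:
    kind: michaelis_menten
    vmax: {value: 32.0, sd: 14.0, unit: nmol/min/mg}
    km: {value: 3244.0, sd: 2646.0, unit: uM}
    protein_basis: microsomal
  HMS:
    kind: first_order
    k: {value: 16.3e-6, unit: ml/min/mg}
    protein_basis: s9
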