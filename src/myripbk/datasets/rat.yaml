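# Male rat parameter set for the myristicin PBK model.
# Physiology after Brown et al.; partition coefficients derived in silico
# (log Kow based); kinetic constants from liver microsomal / S9 incubations.
species: rat
molecular_weight: {value: 192.21, unit: g/mol}
absorption_rate_constant: {value: 1.0, unit: 1/h}
body_weight: {value: 0.25, unit: kg}
cardiac_output: {value: 5.4, unit: L/h}
tissue_volume_fractions:   # of body weight; tissue density 1 g/ml
  liver: {value: 3.4, unit: percent}
  fat: {value: 7.0, unit: percent}
  rapidly_perfused: {value: 5.1, unit: percent}
  slowly_perfused: {value: 60.2, unit: percent}
  blood: {value: 7.4, unit: percent}
flow_fractions:            # of cardiac output
  liver: {value: 25.0, unit: percent}
  fat: {value: 7.0, unit: percent}
  rapidly_perfused: {value: 51.0, unit: percent}
  slowly_perfused: {value: 17.0, unit: percent}
partition_coefficients:    # tissue:blood
  parent:
    liver: 2.49
    fat: 80.41
    rapidly_perfused: 2.49
    slowly_perfused: 0.62
  metabolite_liver: 1.12   # 1'-hydroxymyristicin, liver only
protein_yields:
  microsomal: {value: 35.0, unit: mg/g}
  s9: {value: 143.0, unit: mg/g}
clogp:                     # metadata only, not used in computation
  parent: 3.1721
  metabolite: 1.6151
kinetics_invitro:
  DHM:
    kind: michaelis_menten
    vmax: {value: 0.44, sd: 0.08, unit: nmol/min/mg}
    km: {value: 16.0, sd: 7.0, unit: uM}
    protein_basis: microsomal
  3HM:
    kind: michaelis_menten
    vmax: {value: 0.47, sd: 0.09, unit: nmol/min/mg}
    km: {value: 83.0, sd: 31.0, unit: uM}
    protein_basis: microsomal
  HM:
    kind: michaelis_menten
    vmax: {value: 0.86, sd: 0.18, unit: nmol/min/mg}
    km: {value: 102.0, sd: 32.0, unit: uM}
    protein_basis: microsomal
  DHA:
    kind: michaelis_menten
    vmax: {value: 1.3, sd: 0.23, unit: nmol/min/mg}
    km: {value: 33.0, sd: 11.0, unit: uM}
    protein_basis: microsomal
  HMG:
    kind: michaelis_menten
    vmax: {value: 8.6, sd: 2.0, unit: nmol/min/mg}
    km: {value: 836.0, sd: 336.0, unit: uM}
    protein_basis: s9
  HMO:
    kind: michaelis_menten
    vmax: {value: 43.64, sd: 20.9, unit: nmol/min/mg}
    km: {value: 5922.0, sd: 3477.0, unit: uM}
    protein_basis: microsomal
  HMS:
    kind: first_order
    k: {value: 17.6e-6, unit: ml/min/mg}
    protein_basis: s9
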