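# PBK model parameters, Caucasian population.
population: caucasian
physiology:
  body_weight_kg: 70.0
  tissue_fraction_pct:
    liver: 2.6
    fat: 21.4
    rapidly_perfused: 5.0
    slowly_perfused: 51.7
    blood: 7.9
  cardiac_output_constant: 15.0   # L/h/kg^0.74
  flow_fraction_pct:
    liver: 22.7
    fat: 5.2
    rapidly_perfused: 47.3
    slowly_perfused: 24.8
partition_coefficients:
  estragole:
    liver: 6.5
    fat: 105.0
    rapidly_perfused: 6.5
    slowly_perfused: 4.1
  hydroxyestragole:
    liver: 1.6
absorption:
  ka_per_h: 1.0
protein_yields_mg_per_g_liver:
  microsomes: 35.0
  s9: 143.0
pathways:
  AP:  {protein_source: microsomes, km_uM: 308.0,  km_sem: 71.0,  vmax_invitro: 0.74,  vmax_sem: 0.07}
  EE:  {protein_source: microsomes, km_uM: 146.0,  km_sem: 15.0,  vmax_invitro: 1.85,  vmax_sem: 0.06}
  HE:  {protein_source: microsomes, km_uM: 62.0,   km_sem: 9.0,   vmax_invitro: 1.19,  vmax_sem: 0.04}
  HA:  {protein_source: microsomes, km_uM: 429.0,  km_sem: 80.0,  vmax_invitro: 0.99,  vmax_sem: 0.08}
  M5:  {protein_source: microsomes, km_uM: 1451.0, km_sem: 615.0, vmax_invitro: 1.18,  vmax_sem: 0.34}
  HEG: {protein_source: microsomes, km_uM: 4607.0, km_sem: 878.0, vmax_invitro: 4.29,  vmax_sem: 0.61}
  OE:  {protein_source: s9,         km_uM: 521.0,  km_sem: 265.0, vmax_invitro: 2.8,   vmax_sem: 0.70}
  HES: {protein_source: s9,         km_uM: 423.0,  km_sem: 159.0, vmax_invitro: 0.004, vmax_sem: 0.0005}
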