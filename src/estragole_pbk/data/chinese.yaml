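# PBK model parameters, Chinese population.
# Physiology and partition coefficients from the published parameter table;
# pathway kinetics are the in vitro Michaelis-Menten constants (mean +/- SEM)
# measured in pooled Chinese liver microsomes/S9.
population: chinese
physiology:
  body_weight_kg: 60.0
  tissue_fraction_pct:
    liver: 2.3
    fat: 18.7
    rapidly_perfused: 5.3
    slowly_perfused: 54.3
    blood: 7.9
  cardiac_output_constant: 15.0   # L/h/kg^0.74
  flow_fraction_pct:
    liver: 26.3
    fat: 6.75
    rapidly_perfused: 43.8
    slowly_perfused: 23.3
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
protein_yields_mg_per_g_liver:   # Caucasian-derived yields, used for both populations
  microsomes: 35.0
  s9: 143.0
pathways:
  AP:  {protein_source: microsomes, km_uM: 115.0,  km_sem: 24.0,   vmax_invitro: 0.15,   vmax_sem: 0.01}
  EE:  {protein_source: microsomes, km_uM: 161.0,  km_sem: 17.0,   vmax_invitro: 0.42,   vmax_sem: 0.01}
  HE:  {protein_source: microsomes, km_uM: 49.0,   km_sem: 8.0,    vmax_invitro: 0.35,   vmax_sem: 0.01}
  HA:  {protein_source: microsomes, km_uM: 450.0,  km_sem: 219.0,  vmax_invitro: 0.32,   vmax_sem: 0.07}
  M5:  {protein_source: microsomes, km_uM: 618.0,  km_sem: 164.0,  vmax_invitro: 0.18,   vmax_sem: 0.02}
  HEG: {protein_source: microsomes, km_uM: 4656.0, km_sem: 1247.0, vmax_invitro: 1.63,   vmax_sem: 0.33}
  OE:  {protein_source: s9,         km_uM: 403.0,  km_sem: 137.0,  vmax_invitro: 1.82,   vmax_sem: 0.28}
  HES: {protein_source: s9,         km_uM: 694.0,  km_sem: 321.0,  vmax_invitro: 0.0014, vmax_sem: 0.0002}
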