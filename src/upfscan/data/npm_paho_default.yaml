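# Default nutrient-profile-model configuration (PAHO thresholds).
# Energy-relative criteria use >= semantics; sodium is mg per kcal.
kcal_per_g_sugar: 4.0
kcal_per_g_fat: 9.0
free_sugar_energy_threshold: 0.10
total_fat_energy_threshold: 0.30
sat_fat_energy_threshold: 0.10
trans_fat_energy_threshold: 0.01
sodium_mg_per_kcal_threshold: 1.0
zero_energy_sodium_rule: excess_if_any_sodium
trans_source_keywords:
  - hydrogenated vegetable fat
  - partially hydrogenated fat
  - hydrogenated vegetable oil
  - hydrogenated
  - gordura vegetal hidrogenada
  - gordura parcialmente hidrogenada
  - oleo vegetal hidrogenado
  - hidrogenada
  - hidrogenado
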