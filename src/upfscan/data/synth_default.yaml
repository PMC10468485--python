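# Synthetic-catalog configuration emulating the structure of a large supermarket label census:
# NOVA-group shares 71.9 / 13.7 / 2.4 / 12.0 (%), per-group rates of
# nutrient excess and cosmetic additives, criterion overlap as an odds
# ratio, and the 10.8% voluntary sugar-declaration rate.
n_items: 5000
seed: 42
subgroups:
  # --- Ultra-processed (NOVA 4), total weight 0.719; group-level rates
  # excess 97.1%, cosmetic 82.1%, odds ratio 3.40 (union ~98.8%).
  - name: Sweet cookies
    nova_group: 4
    weight: 0.108
    p_excess: 0.971
    p_cosmetic: 0.821
    odds_ratio: 3.40
    p_additive_class: {flavor: 0.6, color: 0.45, emulsifier: 0.3, thickener: 0.25, preservative: 0.3, antioxidant: 0.15}
  - name: Sweets in general
    nova_group: 4
    weight: 0.180
    p_excess: 0.971
    p_cosmetic: 0.821
    odds_ratio: 3.40
    p_additive_class: {flavor: 0.6, color: 0.5, gelling: 0.2, thickener: 0.2, preservative: 0.25, acidulant: 0.3}
  - name: Dairy beverages
    nova_group: 4
    weight: 0.108
    p_excess: 0.971
    p_cosmetic: 0.821
    odds_ratio: 3.40
    p_additive_class: {flavor: 0.7, color: 0.4, thickener: 0.4, emulsifier: 0.2, preservative: 0.2}
  - name: Carbonated beverages
    nova_group: 4
    weight: 0.072
    p_excess: 0.971
    p_cosmetic: 0.821
    odds_ratio: 3.40
    p_additive_class: {flavor: 0.8, color: 0.5, carbonating: 0.9, acidulant: 0.7, preservative: 0.5}
  - name: Ready meals
    nova_group: 4
    weight: 0.108
    p_excess: 0.971
    p_cosmetic: 0.821
    odds_ratio: 3.40
    p_additive_class: {flavor_enhancer: 0.5, flavor: 0.3, emulsifier: 0.3, thickener: 0.3, preservative: 0.4}
  - name: Sauces and spreads
    nova_group: 4
    weight: 0.143
    p_excess: 0.971
    p_cosmetic: 0.821
    odds_ratio: 3.40
    p_additive_class: {flavor_enhancer: 0.4, color: 0.3, emulsifier: 0.4, thickener: 0.4, preservative: 0.4, acidulant: 0.4}
  # --- Processed (NOVA 3), total weight 0.137; group-level rates
  # excess 90.9%, cosmetic 3.7% (independence).
  - name: Cheese
    nova_group: 3
    weight: 0.069
    p_excess: 0.909
    p_cosmetic: 0.037
    odds_ratio: 1.0
    p_additive_class: {color: 0.8, emulsifying_salt: 0.3, preservative: 0.4}
  - name: Bread
    nova_group: 3
    weight: 0.068
    p_excess: 0.909
    p_cosmetic: 0.037
    odds_ratio: 1.0
    p_additive_class: {emulsifier: 0.6, thickener: 0.3, preservative: 0.5, raising_agent: 0.4}
  # --- Processed culinary ingredients (NOVA 2), weight 0.024; cosmetic 0.4%.
  - name: Animal fats
    nova_group: 2
    weight: 0.024
    p_cosmetic: 0.004
    p_additive_class: {color: 0.9, antioxidant: 0.3}
  # --- Unprocessed/minimally processed (NOVA 1), total weight 0.120;
  # pooled cosmetic ~5.1%, dominated by colorings in pasta.
  - name: Milk
    nova_group: 1
    weight: 0.016
    p_cosmetic: 0.006
    p_additive_class: {color: 0.5, thickener: 0.5}
  - name: Pasta
    nova_group: 1
    weight: 0.0144
    p_cosmetic: 0.382
    p_additive_class: {color: 1.0}
  - name: Grains and others
    nova_group: 1
    weight: 0.0896
    p_cosmetic: 0.005
    p_additive_class: {color: 0.6, antioxidant: 0.2}
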