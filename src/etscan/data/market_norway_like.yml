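# Default synthetic market ("norway-like"): 16 food groups with sizes and
# per-group additive archetypes loosely shaped on a national packaged-food
# assortment (largest group Meat & Poultry; Desserts & Ice Creams and
# Bakery, Cakes & Pastries additive-rich; Infant Food nearly additive-free).
# Archetype mixtures give closed-form marginals and k-way co-occurrence
# probabilities, hence analytic fold enrichments for recovery tests.
# Eight codes (E426, E427, E479b, E483, E493, E494, E495, E499) are given
# zero probability everywhere and so never appear.
seed: 0
style_probs:
  enumber: 0.35
  name: 0.35
  misspelling: 0.15
  subclass: 0.15
defect_rates:
  non_food: 0.010
  no_ingredients: 0.015
  nutrient_gt_100: 0.004
  sugar_gt_carb: 0.004
  satfat_gt_fat: 0.004
  no_energy: 0.004
  energy_gt_4200: 0.003
  bad_kj_kcal_ratio: 0.004
  duplicate: 0.015
default_nutrition: &default_nutrition
  solids_a: 2.0
  solids_b: 3.0
  fat_share: 2.0
  carb_share: 4.0
  protein_share: 2.0
  other_share: 2.0
  sugar_frac_a: 1.5
  sugar_frac_b: 4.0
  satfat_frac_a: 2.0
  satfat_frac_b: 3.0
  salt_med: 0.8
  salt_sigma: 0.6
groups:
  "Desserts & Ice Creams":
    n: 244
    nutrition:
      <<: *default_nutrition
      solids_a: 4.0
      solids_b: 4.0
      fat_share: 3.0
      carb_share: 6.0
      protein_share: 1.0
      other_share: 1.0
      sugar_frac_a: 6.0
      sugar_frac_b: 2.0
      salt_med: 0.2
    archetypes:
      - weight: 0.9
        probs: {E471: 0.60, E412: 0.50, E407: 0.35, E415: 0.30, E440: 0.20,
                E450: 0.15, E466: 0.15, E460: 0.12, E472: 0.20}
      - weight: 0.1
        probs: {}
  "Beverages":
    n: 640
    nutrition:
      <<: *default_nutrition
      solids_a: 1.0
      solids_b: 8.0
      fat_share: 0.3
      carb_share: 7.0
      protein_share: 0.7
      other_share: 2.0
      sugar_frac_a: 5.0
      sugar_frac_b: 2.0
      salt_med: 0.05
    archetypes:
      - weight: 0.25
        probs: {E440: 0.30, E414: 0.25, E415: 0.20, E407: 0.15}
      - weight: 0.75
        probs: {}
  "Fish & Shellfish":
    n: 400
    nutrition:
      <<: *default_nutrition
      fat_share: 2.5
      carb_share: 1.0
      protein_share: 6.0
      salt_med: 1.5
    archetypes:
      - weight: 0.3
        probs: {E412: 0.45, E415: 0.40, E450: 0.35, E451: 0.30, E407: 0.15}
      - weight: 0.7
        probs: {E450: 0.02}
  "Meat & Poultry":
    n: 1760
    nutrition:
      <<: *default_nutrition
      fat_share: 3.0
      carb_share: 1.0
      protein_share: 6.0
      other_share: 2.0
      salt_med: 1.8
    archetypes:
      - weight: 0.26
        probs: {E450: 0.78, E451: 0.72, E452: 0.12, E407: 0.15, E412: 0.10,
                E415: 0.08}
      - weight: 0.74
        probs: {E450: 0.03, E451: 0.02}
  "Fats, Margarine & Spreads":
    n: 240
    nutrition:
      <<: *default_nutrition
      solids_a: 8.0
      solids_b: 2.0
      fat_share: 9.0
      carb_share: 0.5
      protein_share: 0.5
      other_share: 0.5
      salt_med: 0.9
    archetypes:
      - weight: 0.6
        probs: {E471: 0.70, E472: 0.30, E412: 0.35, E415: 0.30}
      - weight: 0.4
        probs: {}
  "Premade Food & Dinner Kits":
    n: 560
    nutrition: *default_nutrition
    archetypes:
      - weight: 0.4
        probs: {E412: 0.40, E415: 0.35, E450: 0.25, E451: 0.20, E471: 0.20}
      - weight: 0.6
        probs: {E412: 0.03}
  "Snacks, Chocolate & Sweets":
    n: 560
    nutrition:
      <<: *default_nutrition
      solids_a: 7.0
      solids_b: 2.0
      fat_share: 4.0
      carb_share: 5.0
      protein_share: 1.0
      sugar_frac_a: 3.0
      sugar_frac_b: 3.0
      salt_med: 1.2
    archetypes:
      - weight: 0.3
        probs: {E471: 0.40, E422: 0.25, E420: 0.20, E472: 0.20}
      - weight: 0.7
        probs: {E471: 0.02}
  "Bakery, Cakes & Pastries":
    n: 980
    nutrition:
      <<: *default_nutrition
      solids_a: 6.0
      solids_b: 3.0
      fat_share: 2.5
      carb_share: 6.0
      protein_share: 1.5
      sugar_frac_a: 2.0
      sugar_frac_b: 3.0
      salt_med: 1.0
    archetypes:
      - weight: 0.75
        probs: {E471: 0.55, E472: 0.40, E412: 0.25, E415: 0.20, E422: 0.15,
                E420: 0.10, E481: 0.08, E466: 0.08}
      - weight: 0.25
        probs: {E471: 0.05}
  "Eggs & Dairy Products":
    n: 800
    nutrition:
      <<: *default_nutrition
      fat_share: 3.0
      carb_share: 2.0
      protein_share: 4.0
      salt_med: 0.6
    archetypes:
      - weight: 0.3
        probs: {E407: 0.30, E440: 0.25, E415: 0.20, E412: 0.20, E450: 0.15}
      - weight: 0.7
        probs: {E407: 0.02}
  "Grains, Baking Mixes & Cereals":
    n: 400
    nutrition:
      <<: *default_nutrition
      carb_share: 7.0
      salt_med: 0.5
    archetypes:
      - weight: 0.25
        probs: {E471: 0.30, E412: 0.25, E466: 0.10}
      - weight: 0.75
        probs: {}
  "Baking Condiments":
    n: 160
    nutrition: *default_nutrition
    archetypes:
      - weight: 0.4
        probs: {E415: 0.35, E412: 0.30, E440: 0.25, E422: 0.20}
      - weight: 0.6
        probs: {}
  "Sauces, Dressings & Other Dinner Condiments":
    n: 480
    nutrition:
      <<: *default_nutrition
      salt_med: 2.0
    archetypes:
      - weight: 0.5
        probs: {E415: 0.60, E412: 0.55, E440: 0.20, E466: 0.15}
      - weight: 0.5
        probs: {E415: 0.05}
  "Processed Fruits & Vegetables":
    n: 320
    nutrition:
      <<: *default_nutrition
      sugar_frac_a: 4.0
      sugar_frac_b: 2.0
      salt_med: 0.4
    archetypes:
      - weight: 0.5
        probs: {E440: 0.45, E415: 0.15, E407: 0.10}
      - weight: 0.5
        probs: {E440: 0.05}
  "Fruit, Vegetables & Legumes":
    n: 400
    nutrition:
      <<: *default_nutrition
      fat_share: 0.5
      salt_med: 0.1
    archetypes:
      - weight: 0.15
        probs: {E440: 0.30, E415: 0.20}
      - weight: 0.85
        probs: {}
  "Infant Food":
    n: 60
    nutrition:
      <<: *default_nutrition
      salt_med: 0.1
    archetypes:
      - weight: 1.0
        probs: {E440: 0.03}
  "Others":
    n: 160
    nutrition: *default_nutrition
    archetypes:
      - weight: 0.3
        probs: {E415: 0.30, E412: 0.25, E471: 0.20, E440: 0.15}
      - weight: 0.7
        probs: {}
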