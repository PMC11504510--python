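# Default NPPM (WHO Europe Nutrient and Promotion Profile Model) ruleset for
# commercial foods for infants and young children aged 6-36 months.
#
# Taxonomy: 14 subcategories nested under 6 product groups, as used for the
# Australian supermarket evaluation.  The Ingredients and Drinks categories are
# supported by the schema but carry no subcategories here (no products were
# identified in the data source for that study).
#
# Thresholds printed in the published evaluation:
#   - sodium <= 50 mg/100 kcal, or <= 100 mg/100 kcal where cheese is named
#   - total sugar <= 15 % of energy
#   - snacks: energy <= 50 kcal per serve
#   - vegetable-only products: added water <= 25 % by weight
#   - fruit subcategory: must contain 100 % fruit
#   - no added free sugars or sweeteners; no industrial trans fats
#   - confectionery: category not permitted
#
# PLACEHOLDER values (verify against NPPM publication) -- not printed in the
# evaluation this package reproduces, deliberately config-level:
#   - minimum energy densities (300 kcal/100 g dry cereals; 60 kcal/100 g for
#     dairy foods, purees and savoury meals)
#   - protein minima (3 g/100 kcal; 4 % by weight where protein/cheese is named)
#   - fat maximum (4.5 g/100 kcal)
#   - high-in-sugar flag threshold (40 % energy from total sugar)
#   - which subcategories carry fruit-content/declaration rules

sugar_energy_factor_kcal_per_g: 4.0
kj_per_kcal: 4.184

subcategories:
  "1.1":
    name: Dry cereals and starches
    group: dry cereals and starches
    energy_density_min_kcal_per_100g: 300.0   # placeholder
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_max_pct_energy: 15.0
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "2.1":
    name: Dairy-based foods, desserts and cereals
    group: dairy foods
    energy_density_min_kcal_per_100g: 60.0    # placeholder
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_max_pct_energy: 15.0
    fruit_declaration_required: true
    protein_min_g_per_100kcal: 3.0            # placeholder
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "2.2":
    name: Yoghurt and cheese-based foods
    group: dairy foods
    energy_density_min_kcal_per_100g: 60.0    # placeholder
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_max_pct_energy: 15.0
    protein_min_g_per_100kcal: 3.0            # placeholder
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "3.1":
    name: Fruit only products
    group: fruit and vegetable purees
    energy_density_min_kcal_per_100g: 60.0    # placeholder
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_flag_threshold_pct_energy: 40.0     # placeholder
    fruit_required_pct: 100.0
    fruit_declaration_required: true
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "3.2":
    name: Vegetable only products
    group: fruit and vegetable purees
    energy_density_min_kcal_per_100g: 60.0    # placeholder
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_flag_threshold_pct_energy: 40.0     # placeholder
    added_water_max_pct: 25.0
    fruit_declaration_required: true
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "3.3":
    name: Mixed fruit and vegetable products
    group: fruit and vegetable purees
    energy_density_min_kcal_per_100g: 60.0    # placeholder
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_flag_threshold_pct_energy: 40.0     # placeholder
    fruit_declaration_required: true
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "3.4":
    name: Fruit-containing products, including breakfast and dairy blends
    group: fruit and vegetable purees
    energy_density_min_kcal_per_100g: 60.0    # placeholder
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_flag_threshold_pct_energy: 40.0     # placeholder
    fruit_declaration_required: true
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "3.5":
    name: Fruit and vegetable smoothie-style blends
    group: fruit and vegetable purees
    energy_density_min_kcal_per_100g: 60.0    # placeholder
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_flag_threshold_pct_energy: 40.0     # placeholder
    fruit_declaration_required: true
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "4.1":
    name: Food with protein named
    group: savoury meals
    energy_density_min_kcal_per_100g: 60.0    # placeholder
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_max_pct_energy: 15.0
    fruit_declaration_required: true
    protein_min_g_per_100kcal: 3.0            # placeholder
    protein_min_pct_weight: 4.0               # placeholder
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "4.2":
    name: Food with cheese named but no protein
    group: savoury meals
    energy_density_min_kcal_per_100g: 60.0    # placeholder
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_max_pct_energy: 15.0
    fruit_declaration_required: true
    protein_min_g_per_100kcal: 3.0            # placeholder
    protein_min_pct_weight: 4.0               # placeholder
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "4.3":
    name: Food without protein or cheese named
    group: savoury meals
    energy_density_min_kcal_per_100g: 60.0    # placeholder
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_max_pct_energy: 15.0
    protein_min_g_per_100kcal: 3.0            # placeholder
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "5.1":
    name: Dry or semi-dry snacks and finger foods
    group: snacks and finger foods
    energy_max_kcal_per_serve: 50.0
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_max_pct_energy: 15.0
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "5.2":
    name: Fruit and vegetable based snacks
    group: snacks and finger foods
    energy_max_kcal_per_serve: 50.0
    sodium_max_mg_per_100kcal: 50.0
    sodium_max_mg_per_100kcal_cheese: 100.0
    sugar_max_pct_energy: 15.0
    fat_max_g_per_100kcal: 4.5                # placeholder
    added_sugar_prohibited: true
    trans_fat_prohibited: true

  "6.1":
    name: Confectionery
    group: confectionery
    category_permitted: false
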