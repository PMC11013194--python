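# Alias map from FFQ-instrument column headers to canonical reference
# parameter names.  Extend per instrument export as needed; unmapped
# columns raise during harmonization rather than being silently dropped.
aliases:
  vioscreen:
    "Alcohol (g)": alcohol
    "Vitamin B12 (mcg)": vitamin_b12
    "Vitamin B6 (mg)": vitamin_b6
    "Beta-Carotene (mcg)": beta_carotene
    "Caffeine (g)": caffeine
    "Total Carbohydrate (g)": carbohydrate
    "Cholesterol (mg)": cholesterol
    "Energy (kcal)": energy
    "Total Fat (g)": total_fat
    "Dietary Fiber (g)": fiber
    "Folic Acid (mcg)": folic_acid
    "Iron (mg)": iron
    "Magnesium (mg)": magnesium
    "MUFA 14:1 (g)": mufa
    "Niacin (mg)": niacin
    "Total Protein (g)": protein
    "Total PUFA (g)": pufa
    "Riboflavin (mg)": riboflavin
    "Total Saturated Fat (g)": saturated_fat
    "Selenium (mcg)": selenium
    "Thiamin (mg)": thiamin
    "Total Trans Fat (g)": trans_fat
    "Vitamin A (RE)": vitamin_a
    "Vitamin C (mg)": vitamin_c
    "Vitamin D (mcg)": vitamin_d
    "Vitamin E (mg)": vitamin_e
    "Zinc (mg)": zinc
  dhqii:
    "alcohol_g": alcohol
    "vitb12_ug": vitamin_b12
    "vitb6_mg": vitamin_b6
    "betacarotene_ug": beta_carotene
    "caffeine_g": caffeine
    "carb_g": carbohydrate
    "chol_mg": cholesterol
    "energy_kcal": energy
    "fat_g": total_fat
    "fiber_g": fiber
    "folicacid_ug": folic_acid
    "iron_mg": iron
    "magnesium_mg": magnesium
    "mufa141_g": mufa
    "niacin_mg": niacin
    "protein_g": protein
    "pufa_g": pufa
    "riboflavin_mg": riboflavin
    "satfat_g": saturated_fat
    "selenium_ug": selenium
    "thiamin_mg": thiamin
    "transfat_g": trans_fat
    "vita_re": vitamin_a
    "vitc_mg": vitamin_c
    "vitd_ug": vitamin_d
    "vite_mg": vitamin_e
    "zinc_mg": zinc
# Multiplicative unit conversions registered for harmonization,
# keyed "<from>-><to>".
unit_conversions:
  "mg->ug": 1000.0
  "ug->mg": 0.001
  "g->mg": 1000.0
  "mg->g": 0.001
  "mcg->ug": 1.0
  "ug->mcg": 1.0
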