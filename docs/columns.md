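# Product table column dictionary

One row per product. Booleans are `true`/`false`; missing values are empty
cells. The JSON format carries the same fields, one object per product, with
`label` nested.

| column | type | notes |
| --- | --- | --- |
| `product_id` | string | unique identifier; used in all outputs |
| `brand` | string | brand name (sampling draws across brands) |
| `name_text` | string | product name as printed on pack |
| `subcategory` | string | NPPM subcategory code (e.g. `3.2`); must exist in the ruleset |
| `product_group` | string | one of the six product groups; must match the subcategory's group |
| `package_type` | string | `pouch`, `jar`, `bowl`, `single-serve packet/sachet`, `multi-serve box/packet` |
| `has_spout` | bool | pouches only |
| `serve_size_g` | number | grams per serve; may be empty (snack energy check then unevaluable) |
| `energy_kcal_per_100g` | number | kcal/100 g. Alternative column `energy_kj_per_100g` (kJ/100 g) is converted at 4.184 kJ/kcal when the kcal column is absent |
| `total_sugar_g_per_100g` | number | g/100 g, ≤ 100 |
| `sodium_mg_per_100g` | number | mg/100 g |
| `protein_g_per_100g` | number | g/100 g (equals % protein by weight) |
| `total_fat_g_per_100g` | number | g/100 g |
| `industrial_trans_fat_present` | bool | from ingredient list |
| `added_free_sugars_present` | bool | added free sugars or sweeteners |
| `fruit_pct` | number | % fruit by weight; empty = not reported (distinct from 0) |
| `added_water_pct` | number | % added water by weight; empty = not reported |
| `fruit_amount_declared` | bool | amount of added fruit declared on label |
| `water_amount_declared` | bool | amount of added water declared on label |
| `cheese_named` | bool | cheese named in product name (raises sodium limit) |
| `protein_named` | bool | protein source named in product name |
| `requires_preparation` | bool | product needs preparation before serving |
| `claims` | string | packed list `category:text;category:text`; categories `compositional`, `nutritional`, `health`, `marketing` |
| `ingredients_descending_order` | bool | ingredient list in descending order |
| `ingredient_list_amounts_complete` | bool | added water/fruit amounts present where applicable |
| `age_min_months` | int | lowest age on label, 0–48; empty if none |
| `age_max_months` | int | upper-age label, 0–48; empty if none |
| `breastfeeding_statement_present` | bool | continued-breastfeeding statement on pack |
| `spoon_or_bowl_suggestion` | bool | pouch suggests serving from spoon/bowl |
| `no_spout_consumption_instruction` | bool | explicit instruction not to consume from the spout |
| `on_the_go_claim_present` | bool | convenience/"on-the-go" claim |
| `preparation_instructions_present` | bool | preparation instructions on pack |
| `preparation_instructions_suitable` | bool | instructions judged suitable |

## Assessment output (long form CSV)

One row per (product, requirement): `product_id`, `part` (`A`/`B`),
`requirement_id`, `applicable`, `passed` (empty when not applicable or not
evaluable), `observed`, `unit`, `threshold`, `deviation_pct` (raw signed %),
`flag_required` (high-sugar flag only), `note`.
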