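# nppm — rule engine for the WHO Nutrient and Promotion Profile Model

Commercial foods for infants and toddlers (purees, meals, snacks in pouches,
jars and boxes, for ages 6–36 months) are widely consumed, often high in
sugar, and heavily marketed. The WHO Regional Office for Europe's **Nutrient
and Promotion Profile Model (NPPM)** sets category-specific requirements for
such products: **Part A** covers composition and content labelling (energy
density, sodium per 100 kcal, % energy from total sugar, added-sugar and
trans-fat prohibitions, fruit/water rules, protein and fat limits, a
"high in sugar" flag), **Part B** covers promotion (no claims, label clarity,
spouted-pouch duties, breastfeeding statement, age labelling).

This package is a config-driven implementation of that assessment for public
health nutrition researchers auditing a product supply: domain types and
readers for flat product tables, the Part A and Part B engines, the
rapid-evaluation sampling protocol (up to five products per subcategory across
brands), and compliance-summary reporting. Because the underlying product
dataset of the evaluation it reproduces was never published, it ships a
deterministic, engineered 45-product fixture whose assessment reproduces every
reported compliance marginal — so every stage is testable without any
download.

The core arithmetic, per product *p* and subcategory rules *r*:

```
sodium per 100 kcal   = Na_mg / E_kcal × 100          (≤ 50, or ≤ 100 if cheese named)
% energy from sugar   = sugar_g × 4.0 / E_kcal × 100  (≤ 15 % where a limit applies)
energy per serve      = E_kcal × serve_g / 100        (≤ 50 kcal, snacks)
deviation             = (observed − threshold) / threshold × 100   (reported half-up)
```

Verdicts compare exact values against inclusive thresholds; only reported
deviations and percentages are rounded (half-up to integer).

## Worked example

```python
from nppm import (assess, default_ruleset, generate_fixture, summarize)

rules = default_ruleset()                 # 14 subcategories, 6 groups
products = generate_fixture(rules)        # engineered 45-product study set
report = summarize(assess(products, rules))

row = report.all_nutrient
print(f"all nutrient requirements met: {row.numerator}/{row.denominator}"
      f" = {row.proportion_pct}%")
sugar = report.requirements["total_sugar"]
print(f"within total sugar limit:      {sugar.numerator}/{sugar.denominator}"
      f" = {sugar.proportion_pct}%")
flag = report.high_sugar_flag_required
print(f"high-in-sugar flag required:   {flag.numerator}/{flag.denominator}"
      f" = {flag.proportion_pct}%")
```

prints

```
all nutrient requirements met: 9/40 = 23%
within total sugar limit:      13/23 = 57%
high-in-sugar flag required:   9/17 = 53%
```

i.e. of the 40 products in permitted categories, 9 (23 %) meet every
applicable Part A threshold; of the 23 subject to the 15 %-energy sugar limit,
13 (57 %) are within it; of the 17 puree-group products screened for the
front-of-pack sugar flag, 9 (53 %) would have to carry it. No product meets
all Part B promotion requirements (`report.all_promotion` is 0/45): every
product carries at least one claim.

The numbered scripts under `analysis/` run the same study end-to-end and
write the product table, long-form per-check results, and summary tables to
`results/`:

```sh
python analysis/01_build_fixture.py
python analysis/02_assess_products.py
python analysis/03_report.py
```

A thin CLI wraps the same functions (`nppm validate | sample | assess |
report | fixture`); see `nppm --help`. Input schema: `docs/columns.md`.
Model details, configuration placeholders and design choices:
`docs/methods.md`.

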