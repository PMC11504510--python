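# Methods

## The model

The WHO Regional Office for Europe's Nutrient and Promotion Profile Model
(NPPM) defines, for food products marketed for infants and young children aged
6–36 months, two families of requirements:

* **Part A — composition and content labelling.** Per-subcategory nutrient
  thresholds: a minimum energy density (kcal/100 g) for most groups or a
  maximum energy per serve for snacks; sodium ≤ 50 mg/100 kcal (≤ 100
  mg/100 kcal where cheese is named in the product name); total sugar ≤ 15 %
  of energy where a sugar limit applies; prohibitions on added free sugars and
  industrial trans fats; added-water and fruit-content rules for vegetable- and
  fruit-based purees; protein minima (g/100 kcal and % by weight) and a fat
  maximum (g/100 kcal); and an informational "high in sugar" front-of-pack
  flag for the puree group. Confectionery is not a permitted category at all.
* **Part B — promotion.** No compositional, nutritional, health or marketing
  claims; product-name and ingredient-list clarity; duties specific to spouted
  pouches (suggest spoon/bowl feeding, instruct against consuming from the
  spout, carry an upper-age label, no "on-the-go" convenience claims); a
  statement on the importance of continued breastfeeding to 2 years or beyond;
  no age labels below 6 months; suitable preparation instructions where
  preparation is required.

All normalisations are elementary: sodium (and protein, fat) per 100 kcal is
`amount_per_100g / energy_per_100g × 100`; the sugar energy share is
`sugar_g × 4.0 / energy_kcal × 100` (the 4.0 kcal/g factor is configurable —
the model expresses the limit as a share of energy without fixing a factor);
energy per serve is `energy_per_100g × serve_g / 100`. Reported deviations are
`(observed − threshold) / threshold × 100`, signed, and rounded **half-up** to
integer percent for reporting only — verdicts always compare exact values.
Thresholds are inclusive (`observed ≤ max` passes, `observed ≥ min` passes),
matching how the limits are written.

## Rule configuration

Every threshold the engines consult lives in a YAML ruleset
(`src/nppm/data/nppm_default.yaml`); engine code contains no literal limits
(a test mutates the config and watches verdicts flip). A threshold a
subcategory does not define makes the check *not applicable*, never zero.
Thresholds the reproduced evaluation prints are authoritative defaults; values
it does not print — the minimum energy densities (300 kcal/100 g for dry
cereals, 60 kcal/100 g elsewhere), the protein minima (3 g/100 kcal; 4 % by
weight), the fat maximum (4.5 g/100 kcal), the high-sugar-flag threshold
(40 % energy), and exactly which subcategories carry fruit rules — ship as
documented placeholders flagged in the config for verification against the
NPPM publication. They are config-level precisely so a corrected value never
requires a code change.

## Verdict bookkeeping

Each requirement on each product yields a `CheckResult` with `applicable`,
`passed` (missing when not applicable or when inputs are insufficient, e.g. a
snack without a declared serve size — such checks are excluded from both
numerator and denominator and logged), observed value, threshold, and the raw
signed deviation. "Meets all nutrient requirements" is the conjunction over
applicable, evaluable Part A checks, excluding the informational high-sugar
flag; the flag is tallied separately as required / evaluable. Summary
proportions are always reported on applicable denominators. Per-package-type
compliance pools *all* applicable Part A and Part B checks across the
products of each type (this scope choice is recorded in the run metadata).

## Sampling

The rapid-evaluation protocol selects up to five products per subcategory
across brands: when a subcategory holds at most five products, all are taken;
otherwise one product is drawn uniformly per brand and remaining slots are
filled uniformly from the rest. The protocol leaves the >5-brands case open;
this implementation draws a uniform subset of five brands, one product each,
preserving the one-per-brand spirit within the cap. All randomness flows
through one seeded NumPy generator, so a seed fully determines the sample.

## The synthetic study set

The evaluation this package reproduces assessed 45 real supermarket products,
but the per-product dataset was never published. The packaged fixture is an
*engineered* stand-in: 45 products across the six product groups and fourteen
subcategories, with 16 spouted pouches (8 savoury meals, 4 purees, 4 dairy),
constructed so that assessment under the default ruleset reproduces every
reported marginal exactly — 9/40 meeting all nutrient requirements (23 %),
21/40 energy (53 %), 38/40 sodium (95 %), 13/23 sugar (57 %), 34/40 added
sugar (85 %), 28/30 fruit (93 %), 15/19 protein content (79 %), 6/10 protein
weight (60 %), 39/40 fat (98 %), 9/17 flag-required (53 %), 0/45 promotion
compliant, 27/45 name-clarity and 16/45 ingredient-clarity failures, 3/16
pouches with a no-spout instruction, 0/45 breastfeeding statements, 3/45
"from 4 months" labels, 5/5 suitable preparation instructions — together with
the individual reported deviation extremes (added water 42.8 % → +71 %;
fruit 99.5 % vs 100 %; sodium +38 % and +7 %; sugar +16 %…+97 %; fat +16 %;
energy −0.1 %…−48 %). Group sizes (1 dry-cereal, 5 dairy, 17 puree, 14
savoury-meal, 3 snack, 5 confectionery products) are forced by the interplay
of the reported denominators: the sugar-limit subjects (23) and flag subjects
(17) partition the 40 permitted-category products, protein-content subjects
(19) are the dairy and savoury-meal groups, protein-weight subjects (10) are
the two protein/cheese-named meal subcategories, and four protein-content
failures must fit inside the "no protein or cheese named" subcategory.
Nutrient values for compliant products sit mid-range between thresholds;
violators sit at the reported extremes where reported, otherwise at documented
offsets.

Generation is self-verifying: the builder assesses its own output and raises
a `GenerationError` naming any marginal that does not match its target — so
calling it with a ruleset the table was not engineered against fails loudly
rather than silently shifting the marginals.

What passing on this fixture shows: that the engines, the applicability
logic, the rounding convention, and the reporter jointly reproduce the
published arithmetic. What it cannot show: anything about the real product
supply — the fixture's brands, names, and unconstrained cell values are
synthetic, and its package-type compliance outside the pouch stratum is not
constrained (only the pooled pouch figure, 55 %, is reproduced; the jar and
bowl strata land where the engineered table puts them).

The randomised generator (`generate_random`) draws compliant baselines per
subcategory and injects violations per requirement with configured
probabilities. Injections are requirement-local except where composition
couples checks: protein weight and protein content both derive from one
protein field, so a content violation in a weight-bearing subcategory drags
the weight check down with it (the weight-violation injector, conversely,
stays above the content minimum where feasible). Zero probabilities must give
100 % compliance on every applicable check — a soundness probe for the
engines — and empirical rates at n = 1000 are tested against two-sided 99 %
binomial bounds.

## Numerical choices and degenerate inputs

* Rounding is half-up (decimal, ties away from zero), not banker's: the
  reported integer percentages require 22.5→23, 52.5→53, 56.5→57, 97.5→98.
* Zero energy makes per-100 kcal and %-energy quantities undefined: the
  formula helpers raise, and the engine records an insufficient-input verdict
  instead.
* Missing optional amounts (`fruit_pct`, `added_water_pct`) are explicit
  `None`, never 0 — an undeclared fruit amount is itself a fruit-rule failure
  where declaration is required, and a missing added-water figure yields a
  missing verdict, not a pass.
* Energy supplied in kJ is converted at 4.184 kJ/kcal only when the kcal
  column is absent.
* Claim categories are taken from the input table; the regex lexicon tagger
  is opt-in assistance only, with `marketing` as the fallback category.

## Problem sizes

The deterministic fixture has n = 45; property suites use 1000 randomly
generated products for oracle equivalence and rate calibration and a few
hundred for soundness probes. These sizes keep the whole suite and the
acceptance script in the tens of seconds while leaving the binomial bounds
tight enough to detect a miscalibrated generator.

## Known limitations

* The NPPM Part B inventory here covers the requirements the reproduced
  evaluation scored; further NPPM items (e.g. full product-name composition
  rules) need manual annotation inputs and are represented only by the
  machine-checkable flags.
* Name clarity is reduced to the ingredient-ordering flag; semantic adequacy
  of a breastfeeding statement's wording is presence-only.
* Visual/child-appeal marketing cues are outside the model and the package.
* Micronutrient rules from national codes (e.g. iron in cereals) are out of
  scope.
* The sugar checks evaluate *total* sugar, as the reproduced evaluation did;
  subcategory-specific free-sugar variants would be a config extension.
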