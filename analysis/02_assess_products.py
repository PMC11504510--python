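#!/usr/bin/env python
"""Assess the study set against the default NPPM ruleset.

Reads results/fixture_products.csv (run 01_build_fixture.py first), evaluates
every product against Part A (composition) and Part B (promotion), and writes
the long-form per-check results.  Prints the headline findings.
"""

from pathlib import Path

from nppm import assess, default_ruleset, read_products, write_assessments

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    products = read_products(OUT / "fixture_products.csv")
    rules = default_ruleset()
    assessments = assess(products, rules)
    write_assessments(assessments, OUT / "assessments.csv")
    write_assessments(assessments, OUT / "assessments.json")

    n = len(assessments)
    nutrient_ok = sum(1 for a in assessments if a.meets_all_nutrient)
    promo_ok = sum(1 for a in assessments if a.meets_all_promotion)
    flagged = sum(1 for a in assessments if a.high_sugar_flag_required)
    print(f"assessed {n} products")
    print(f"  meets all nutrient requirements : {nutrient_ok}")
    print(f"  meets all promotion requirements: {promo_ok}")
    print(f"  would need a high-in-sugar flag : {flagged}")
    print(f"-> {OUT / 'assessments.csv'}")


if __name__ == "__main__":
    main()
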