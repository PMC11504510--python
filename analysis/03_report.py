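#!/usr/bin/env python
"""Aggregate the assessments into the compliance summary tables.

Writes the per-requirement summary (numerator / denominator / % met, half-up)
and the per-package-type compliance fractions, as CSV and markdown.
"""

from pathlib import Path

import pandas as pd

from nppm import (
    assess,
    default_ruleset,
    package_type_compliance,
    read_products,
    summarize,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    products = read_products(OUT / "fixture_products.csv")
    assessments = assess(products, default_ruleset())
    report = summarize(assessments)
    report.package_type = package_type_compliance(assessments, products)

    rows = [
        {"requirement_id": req, "met": num, "subject_to": den, "pct_met": pct}
        for req, num, den, pct in report.to_rows()
    ]
    pd.DataFrame(rows).to_csv(OUT / "summary.csv", index=False)
    (OUT / "summary.md").write_text(report.to_markdown() + "\n")

    print(report.to_markdown())
    print(f"\n-> {OUT / 'summary.csv'}, {OUT / 'summary.md'}")


if __name__ == "__main__":
    main()
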