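#!/usr/bin/env python
"""Build the engineered 45-product study set and write it to results/.

The real supermarket sample was never deposited, so the study set is the
deterministic fixture: 45 products across 6 product groups and 14 NPPM
subcategories, engineered so that its assessment reproduces every reported
compliance marginal.  Writes the product table and a provenance note mapping
each engineered constraint to the reported count it encodes.
"""

import json
from pathlib import Path

from nppm import generate_fixture, write_products
from nppm.synthetic import fixture_provenance

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    products = generate_fixture()
    write_products(products, OUT / "fixture_products.csv")
    (OUT / "fixture_provenance.json").write_text(json.dumps(fixture_provenance(), indent=1))
    pouches = sum(1 for p in products if p.package_type == "pouch")
    groups = sorted({p.product_group for p in products})
    print(f"wrote {len(products)} products ({pouches} pouches) across {len(groups)} groups")
    print(f"-> {OUT / 'fixture_products.csv'}")


if __name__ == "__main__":
    main()
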