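# Ordered pattern -> category lexicon for assistive claim tagging.
# First match wins; anything unmatched defaults to "marketing".
- pattern: "source of (protein|fibre|fiber|iron|calcium)"
  category: nutritional
- pattern: "no added (sugar|salt)"
  category: nutritional
- pattern: "high in (fibre|fiber|protein|iron)"
  category: nutritional
- pattern: "(good|excellent) source of"
  category: nutritional
- pattern: "supports? .*(growth|development|immunity)"
  category: health
- pattern: "good for .*(gut|teeth|bones|brain)"
  category: health
- pattern: "probiotic|prebiotic"
  category: health
- pattern: "100\\s*% (fruit|vegetable|natural)"
  category: compositional
- pattern: "made with real"
  category: compositional
- pattern: "organic"
  category: compositional
- pattern: "no (preservatives|artificial|nasties)"
  category: marketing
- pattern: "for tiny hands"
  category: marketing
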