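"""Tag a handful of supplement product names and normalize them.

Each name is decomposed into typed spans (brand, ingredient, strength,
dose form, ...), summarized as a template of term-type codes, mapped to
an RxNorm term type where one exists, and rewritten in normalized form
(canonical keyword spellings, template order, stop words dropped).
"""

from dsnorm import (
    compile_rules,
    derive_template,
    load_demo_lexicon,
    map_to_rxnorm,
    normalize_name,
    tag_name,
)

NAMES = [
    "Herb Pharm Elderberry",
    "Bronson Laboratories Vitamin E 200 IU",
    "Optimum Nutrition Tribulus 625 MG Caps",
    "Nature's Answer Hawthorn Berry",
    "Solgar Zinc with Lemon",
]

rules = compile_rules(load_demo_lexicon())

for name in NAMES:
    tagged = tag_name(name, rules)
    template = derive_template(tagged)
    rxnorm = map_to_rxnorm(template) or "-"
    print(f"{name}")
    for span in tagged.spans:
        print(f"  [{span.term_type:>4}] {span.text!r} -> {span.canonical}")
    print(f"  template: {template}   rxnorm: {rxnorm}   status: {tagged.status}")
    print(f"  normalized: {normalize_name(tagged)}")
    print()

# The template is the name's structure: "BN IN STR" reads brand +
# ingredient + strength, which corresponds to RxNorm's SBDC.  Names
# whose structure has no RxNorm counterpart (e.g. "BN IN") show "-".
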