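# dsnorm

Rule-based normalization of dietary-supplement product names using an
RxNorm-style term-type model.

## The problem

Dietary-supplement labeling rules are loose, so the same product can be
named "Elderberry 100mg Caps", "Herb Pharm Elderberry", or "Natural
Elderberry Extract with Vitamin C" — brand, ingredient, dose and
marketing copy mixed in no fixed order. Clinical drugs solved this with
RxNorm, which names every drug as a composition of typed parts:
ingredient (IN), brand name (BN), strength (STR), dose form (DF), and
composites such as SBDC = BN + IN + STR. `dsnorm` applies the same idea
to supplement names, for anyone building pharmacovigilance, knowledge
bases, or search over supplement products.

A product name *n* is decomposed by ordered dictionary and regex rules
into non-overlapping typed spans. The ordered list of span types, with
stop words dropped, is the name's **template**:

```
Bronson Laboratories Vitamin E 200 IU
[------ BN --------] [- IN --] [STR ]   →   template BN IN STR  (RxNorm SBDC)
```

Fourteen term types exist (13 content types + STOP). Templates whose
structure matches one of the ten applicable RxNorm composite term types
map onto it; the most common supplement structure without an RxNorm
counterpart is plain `BN IN`.

Tagging accuracy is scored token-wise against binary span labels:

```
accuracy(n) = (1/|T(n)|) · Σ_{t ∈ T(n)} ℓ(t)
```

where T(n) are the name's tokens and ℓ(t) ∈ {0, 1}, every token outside
a labeled span scoring 0. Corpus accuracy is the unweighted mean over
names, reported overall and for the fully / partially matched strata.

## Worked example

```python
from dsnorm import (compile_rules, derive_template, load_demo_lexicon,
                    map_to_rxnorm, normalize_name, tag_name)

rules = compile_rules(load_demo_lexicon())
tagged = tag_name("Optimum Nutrition Tribulus 625 MG Caps", rules)
for span in tagged.spans:
    print(f"[{span.term_type:>4}] {span.text!r} -> {span.canonical}")
template = derive_template(tagged)
print(template, map_to_rxnorm(template), tagged.status)
print(normalize_name(tagged))
```

prints

```
[  BN] 'Optimum Nutrition' -> Optimum Nutrition
[  IN] 'Tribulus' -> Tribulus
[ STR] '625 MG' -> 625 mg
[  DF] 'Caps' -> Capsule
BN IN STR DF SBD full
Optimum Nutrition Tribulus 625 mg Capsule
```

The four spans cover every token, so the match status is `full`; the
structure brand + ingredient + strength + dose form corresponds to
RxNorm's Semantic Branded Drug (SBD); and the normalized form replaces
the abbreviation "Caps" with its canonical dose form "Capsule".

The scripts in `examples/` walk through each capability: tagging and
normalization, building and auditing a lexicon, generating a synthetic
gold-annotated corpus, and computing coverage and accuracy reports.

## Command line

The same pipeline is available as a thin CLI:

```bash
dsnorm tag names.txt --out tagged.jsonl          # spans + template per name
dsnorm generate --n 1000 --seed 7 --out names.txt --gold gold.tsv
dsnorm evaluate --pred tagged.jsonl --gold gold.tsv
dsnorm report --pred tagged.jsonl                # template frequency table
```

Inputs are UTF-8 text with one product name per line; tagged output is
JSON-lines; gold annotations and reports are TSV. Lexicons are 4-column
TSV (surface, canonical, term_type, source) — see
`src/dsnorm/data/demo_lexicon.tsv` for the bundled, field-by-field
documented demo lexicon.

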