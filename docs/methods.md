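# Methods

This note documents the model behind `dsnorm`, the choices made where
the design was genuinely open, and what the synthetic corpus does and
does not establish about real supplement names.

## The term-type model

A supplement product name is treated as a sequence of typed components
in the style of RxNorm's drug-name model. Fourteen term types are
defined: BN (brand), IN (ingredient), STR (strength), DF (dose form),
DFG (dose-form group), PLNT (plant part), PREP (preparation), ANM
(animal source), FLV (flavor), POP (population), CERT (certification),
TIM (time of use), USE (claim/use), and STOP (stop word). The ordered
list of a name's span types with STOP removed is its **template**; a
template is the unit of normalization. Ten templates correspond
structurally to RxNorm composite term types (IN, SCDC, SCDF, SCDG,
SCD, BN, SBDC, SBDF, SBDG, SBD); the mapping ships as a data file and
is an exact lookup. Pack and multi-ingredient RxNorm codes (GPCK,
BPCK, MIN, PIN) do not apply to single-ingredient supplement names and
never appear.

## Matching procedure

Names are tokenized on whitespace; edge punctuation is stripped from
tokens while original character offsets are kept, and curly apostrophes
are folded to ASCII for matching only. All matching is case-insensitive
and aligned to token boundaries (whether raw-substring matching would
behave differently is untested; token alignment is this package's
choice, as is longest-match preference among nested multi-word
surfaces such as "green tea" vs. "tea").

Rules are applied in a fixed priority order — BN, IN, STR, DF, DFG,
PLNT, PREP, ANM, FLV, POP, CERT, TIM, USE, STOP — and each rule may
only claim characters no earlier rule has claimed. Brands precede
ingredients, and both precede everything else, because they overlap
other types the most; USE, the most open-ended content type, comes
last among content types; STOP comes last of all so content rules get
first claim. Within one rule, candidates are claimed longest first
(token count, then character length), ties going to the leftmost. This
greedy procedure is verified in the test suite against a brute-force
oracle that enumerates every consistent span assignment on short names
and picks the one maximizing per-rule coverage lexicographically in
priority order.

Three non-dictionary matchers exist:

* **Strength**: a number (decimal point and thousands commas allowed)
  followed by a unit — mg, mcg, µg, g, kg, IU, ml, l, % or
  "billion CFU" — attached ("200mg") or separated ("200 IU"). The
  number is required so that the unit string "mg" can never fire
  inside a word like "Magnesium". The unit list extends the obviously
  attested milligram/IU cases to the units seen on supplement labels.
* **Vitamin**: the word "vitamin" followed by a designator (A, B,
  B1–B12, C, D, D3, E, K, K2) is an ingredient, e.g. "Vitamin E".
* **Brand heuristic** (toggleable, on by default): a name-initial run
  of up to three capitalized tokens that precede the first token any
  other rule could match is claimed as BN. Leading position is the
  dominant brand pattern on supplement labels; the cap of three
  bounds the damage on all-capitalized junk names, and the toggle
  exists because the heuristic trades precision for coverage.

By default at most one ingredient span is kept per name — the
single-ingredient case is the modeled one. "One" means the first span
the matcher claims, i.e. the longest (leftmost on ties): keeping the
leftmost mention instead would break the greedy/oracle equivalence
above on names like "Tea Green Tea", where the leftmost mention is a
strictly weaker match. A `multi_ingredient` flag lifts the cap, and
duplicate codes are then preserved adjacently in the template.

A name's status is **full** when every token is claimed and at least
one content span exists, **none** when no content span exists (a name
of nothing but stop words is `none`), **partial** otherwise.

Templates are order-normalized: span types are reordered into the
canonical order BN, IN, STR, DF, DFG, PLNT, PREP, ANM, FLV, POP, CERT,
TIM, USE rather than kept in surface order, so equal multisets of
codes always yield equal templates and composite RxNorm structures
read off directly. Normalized output joins the canonical keyword forms
in that same order.

## Lexicons

Lexicons are 4-column TSV (surface, canonical, term_type, source) or
the equivalent JSON; surfaces are stored lowercased, canonicals keep
their casing, and the canonical defaults to the surface. Variant
expansion adds plurals (+s, +es after s/x/z/ch/sh) and a small curated
abbreviation table (cap/caps → capsule, tab/tabs → tablet, oz → ounce,
tsp, tbsp, lb/lbs); variants inherit the base entry's canonical form
and are tagged in their source field, which makes expansion
idempotent. Stop words and possessives are not pluralized. A collision
report lists every surface registered under two or more term types
(e.g. "heart" as animal source vs. claim); ambiguity between types is
otherwise resolved only by rule priority, not by context.

The bundled demo lexicon (~90 base entries) is a hand-curated stand-in
for full keyword lists; it is deliberately collision-free so that
generated corpora have a unique correct tagging.

## Evaluation

Every predicted (span, term type) pair carries a binary correctness
label; gold files are TSV keyed by 0-based half-open character
offsets, mirroring the tagger's output. The accuracy of a name is the
mean of its token labels: a token inside a labeled span inherits the
span's label, a token in no span counts 0, and a predicted span absent
from the gold counts 0. Tokens claimed by a STOP span are excluded
from the denominator — stop words are removed from names before
matching and carry no information about tagging quality; this also
makes a correctly tagged name score exactly 1.0 regardless of how many
stop words it contains. A zero-token name has no defined accuracy and
raises.

Corpus accuracy is the unweighted mean of per-name accuracies (the
defining equation averages names, not tokens), reported overall and
for the full-only and partial-only strata. Per-term-type accuracy is
the mean span label of that type over fully and partially matched
names; status-none names have no spans to score and are excluded from
the per-type denominators while still counting (as 0) in the overall
mean.

## The synthetic corpus

Real label corpora cannot be redistributed, so the generator emulates
the naming conventions the model targets: a brand prefix, exactly one
ingredient, and optional strength / dose-form / plant-part / flavor /
claim suffixes, with stop words inserted between slots and a
configurable fraction of out-of-lexicon brands. Default template
weights are BN IN STR 0.320, BN IN 0.213, BN IN DF 0.034, BN IN STR DF
0.030, BN IN PLNT 0.019 — the dominant structures of single-ingredient
supplement names at realistic proportions — with the remaining 0.384
split evenly between BN IN USE and BN IN FLV so that templates without
an RxNorm counterpart are exercised. Strengths are drawn as an integer
in [5, 2000] with a unit from {mg, mcg, g, IU, ml}, spanning typical
label strengths. Stop-insertion and OOV-brand probabilities default to
0.1 each: most names stay fully resolvable while partial matches and
brand misses occur, roughly like a held-out set facing an incomplete
brand list. Gold spans exactly tile the non-stop, non-OOV tokens with
label 1 — OOV brands get no gold span, recording only what dictionary
knowledge could have found.

Each record's stratum defaults to the first two codes of its template,
standing in for a product-type classification, so the stratified
80/20 splitting machinery is exercised even though real product-type
codes are unavailable. Splitting shuffles within each stratum under a
seed and rounds stratum × fraction to the nearest integer.

What passing tests on this corpus show: the matcher recovers exactly
the structure the generator planted (100% template recovery and
self-evaluation accuracy 1.0 on clean corpora), degrades monotonically
as OOV brands are added, and the metrics behave as defined. What they
do not show: performance on real label text, whose brand vocabulary,
multi-ingredient names, polysemous keywords, misspellings, and
free-form marketing copy the generator does not emulate. Coverage and
accuracy on real corpora depend almost entirely on lexicon
completeness, which a demo lexicon cannot represent.

## Numerical and procedural choices

* Offsets are 0-based, half-open, everywhere (spans, gold files,
  JSON-lines output).
* Coverage fractions share the corpus size as denominator and sum
  to 1 within 1e-9; coverage of an empty corpus raises rather than
  returning NaNs.
* Generation and splitting are deterministic in their integer seeds
  (`random.Random`); tagging is fully deterministic.
* Duplicate (surface, term_type) lexicon rows keep the first
  occurrence; hand-listed entries always beat generated variants.
* Test problem sizes: round-trip and distributional properties are
  checked at n = 10,000 generated names, invariant sweeps at
  n = 500–2,000 — large enough for three-sigma binomial bounds on the
  0.32 dominant-template share while keeping the suite fast.

## Known limitations

* No context disambiguation: a polysemous keyword is always claimed
  by the highest-priority rule that reaches it first.
* Brand detection is dictionary + leading-capitalization heuristic;
  novel brands in non-initial position are missed, and capitalized
  junk at the start of a name can be mistaken for a brand.
* Single-ingredient assumption by default; the multi-ingredient flag
  only lifts the span cap, it does not add conjunction-aware parsing.
* Surface matching is exact after case folding; no fuzzy or
  misspelling-tolerant matching.
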