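"""Build a lexicon from scratch, expand variants, audit collisions.

Keyword lists are the knowledge behind the tagger.  This example
assembles a tiny one in code, shows what variant expansion adds
(plurals and curated abbreviations, all inheriting the canonical
form), and runs the collision audit that flags surfaces registered
under more than one term type — the main source of tagging ambiguity.
"""

from dsnorm import Lexicon, LexiconEntry, collision_report, compile_rules, tag_name

entries = [
    LexiconEntry("pure encapsulations", "Pure Encapsulations", "BN", "annotation"),
    LexiconEntry("milk thistle", "Milk Thistle", "IN", "thesaurus"),
    LexiconEntry("capsule", "Capsule", "DF", "vocabulary"),
    # deliberately ambiguous: a body part that reads like a health claim
    LexiconEntry("heart", "Heart", "ANM", "vocabulary"),
    LexiconEntry("heart", "Heart", "USE", "annotation"),
]
lexicon = Lexicon(entries).expanded()

print(f"{len(entries)} base entries -> {len(lexicon)} after variant expansion")
for e in lexicon.entries_for("DF"):
    print(f"  DF surface {e.surface!r} -> canonical {e.canonical!r}")
print()

print("ambiguous surfaces:", collision_report(lexicon))
print()

tagged = tag_name("Pure Encapsulations Milk Thistle 60 Caps", compile_rules(lexicon))
print("60 Caps name:", [(s.term_type, s.text) for s in tagged.spans], tagged.status)

# "Caps" matched via the abbreviation variant and normalizes back to
# "Capsule"; the bare count "60" is no strength (no unit follows the
# number), so it stays unmatched and the name is only partially
# matched.  "heart" stays ambiguous until the rule priority order
# (ANM before USE) decides which matcher claims it first.
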