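"""Tokenization, rule priority, span claiming, and the matching oracle."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsnorm import (
    Lexicon,
    LexiconEntry,
    RuleConfig,
    compile_rules,
    derive_template,
    load_demo_lexicon,
    tag_name,
    tokenize,
)
from dsnorm.tagger import _NUMBER_RE, _UNIT_RE
from conftest import WORKED_EXAMPLES

# Module-level rule sets for the hypothesis suites (fixtures cannot be
# mixed with @given at function scope).
_DEMO_RULES = compile_rules(load_demo_lexicon())
_DEMO_RULES_NH = compile_rules(load_demo_lexicon(), RuleConfig(brand_heuristic=False))


class TestTokenize:
    def test_two_word_name(self):
        assert len(tokenize("NutraBio Melatonin")) == 2

    def test_empty_string(self):
        assert tokenize("") == []

    def test_punctuation_stripped_but_offsets_original(self):
        name = "Vitamin E, 200 IU"
        tokens = tokenize(name)
        assert [t.text for t in tokens] == ["Vitamin", "E", "200", "IU"]
        for t in tokens:
            assert name[t.start:t.end] == t.text

    def test_internal_apostrophe_kept(self):
        (tok,) = tokenize("Nature's")
        assert tok.text == "Nature's"

    @given(st.text(max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_offsets_always_index_the_source(self, name):
        for t in tokenize(name):
            assert 0 <= t.start < t.end <= len(name)
            assert name[t.start:t.end] == t.text


class TestRuleCompilation:
    def test_brand_rule_precedes_ingredient_rule(self, default_rules):
        assert default_rules.rule_position("BN") < default_rules.rule_position("IN")

    def test_ingredient_precedes_remaining_content_types(self, default_rules):
        pos_in = default_rules.rule_position("IN")
        for tt in ("STR", "DF", "PLNT", "PREP", "USE", "STOP"):
            assert pos_in < default_rules.rule_position(tt)

    def test_empty_lexicon_keeps_regex_rules(self):
        rules = compile_rules(Lexicon())
        kinds = {r.rule_id for r in rules.rules}
        assert kinds == {"IN:vitamin", "STR:regex"}

    def test_strength_regex_requires_number_and_unit(self):
        """Enumerate the strength matcher over token bigrams of the
        worked-example names: exactly the number+unit bigrams fire."""
        for name, _ in WORKED_EXAMPLES:
            tokens = [t.norm for t in tokenize(name)]
            for a, b in zip(tokens, tokens[1:]):
                fires = bool(_NUMBER_RE.fullmatch(a) and _UNIT_RE.fullmatch(b))
                expected = (a, b) in {("200", "iu"), ("625", "mg")}
                assert fires == expected, (name, a, b)


class TestTagName:
    @pytest.mark.parametrize("name, template", WORKED_EXAMPLES)
    def test_worked_examples_fully_matched(self, default_rules, name, template):
        tagged = tag_name(name, default_rules)
        assert tagged.status == "full"
        assert str(derive_template(tagged)) == template

    def test_bare_magnesium_is_ingredient_not_strength(self, default_rules):
        tagged = tag_name("Magnesium", default_rules)
        assert [s.term_type for s in tagged.spans] == ["IN"]

    def test_mg_fires_only_after_a_number(self, default_rules):
        tagged = tag_name("Magnesium 200 mg", default_rules)
        types = {s.term_type: s.text for s in tagged.spans}
        assert types == {"IN": "Magnesium", "STR": "200 mg"}

    def test_unknown_words_without_heuristic_are_unmatched(self, no_heuristic_rules):
        tagged = tag_name("Zxqwv Unknownword", no_heuristic_rules)
        assert tagged.status == "none"
        assert tagged.spans == ()

    def test_heuristic_tags_leading_capitalized_unknowns(self, default_rules):
        tagged = tag_name("Zorvex Labs Melatonin", default_rules)
        bn = [s for s in tagged.spans if s.term_type == "BN"]
        assert len(bn) == 1 and bn[0].text == "Zorvex Labs"
        assert bn[0].rule_id == "BN:heuristic"

    def test_heuristic_stops_at_first_other_match(self, default_rules):
        tagged = tag_name("Zorvex Melatonin Powder", default_rules)
        bn = [s for s in tagged.spans if s.term_type == "BN"]
        assert [s.text for s in bn] == ["Zorvex"]
        assert tagged.status == "full"

    def test_longest_surface_wins_within_a_rule(self, default_rules):
        tagged = tag_name("Solgar Green Tea", default_rules)
        in_spans = [s for s in tagged.spans if s.term_type == "IN"]
        assert [s.text for s in in_spans] == ["Green Tea"]

    def test_single_ingredient_cap_and_multi_ingredient_flag(self, demo_lexicon):
        name = "Solgar Garlic and Cayenne"
        single = tag_name(name, compile_rules(demo_lexicon))
        # One ingredient kept by default: the strongest (longest) match.
        assert [s.text for s in single.spans if s.term_type == "IN"] == ["Cayenne"]
        assert single.status == "partial"
        multi = tag_name(
            name, compile_rules(demo_lexicon, RuleConfig(multi_ingredient=True))
        )
        assert [s.text for s in multi.spans if s.term_type == "IN"] == \
            ["Garlic", "Cayenne"]
        assert multi.status == "full"

    def test_stop_words_matched_but_excluded_from_status(self, default_rules):
        tagged = tag_name("Solgar Zinc with Lemon", default_rules)
        assert tagged.status == "full"
        assert {s.term_type for s in tagged.spans} == {"BN", "IN", "STOP", "FLV"}

    def test_all_stop_words_means_no_match(self, default_rules):
        assert tag_name("with and the", default_rules).status == "none"

    def test_attached_strength_unit(self, default_rules):
        tagged = tag_name("Solgar Zinc 200mg", default_rules)
        str_spans = [s for s in tagged.spans if s.term_type == "STR"]
        assert [s.canonical for s in str_spans] == ["200 mg"]

    def test_billion_cfu_strength(self, default_rules):
        tagged = tag_name("Solgar Zinc 5 billion CFU", default_rules)
        str_spans = [s for s in tagged.spans if s.term_type == "STR"]
        assert [s.text for s in str_spans] == ["5 billion CFU"]


# --- property suites --------------------------------------------------

WORD_POOL = [
    "Solgar", "GNC", "Green", "Tea", "Zinc", "Melatonin", "Powder",
    "Capsule", "Leaf", "Berry", "Extract", "with", "the", "200", "mg",
    "IU", "Vitamin", "E", "Unknownword", "Blargle",
]

names_from_pool = st.lists(
    st.sampled_from(WORD_POOL), min_size=0, max_size=6
).map(" ".join)


@given(names_from_pool)
@settings(max_examples=300, deadline=None)
def test_spans_never_overlap(name):
    tagged = tag_name(name, _DEMO_RULES)
    spans = sorted(tagged.spans, key=lambda s: s.start)
    for a, b in zip(spans, spans[1:]):
        assert a.end <= b.start


@given(names_from_pool)
@settings(max_examples=300, deadline=None)
def test_span_tokens_plus_unmatched_reconstruct_the_name(name):
    """Every token is either inside exactly one span or unmatched."""
    tagged = tag_name(name, _DEMO_RULES)
    tokens = tokenize(name)
    covered = [
        t for t in tokens if any(s.covers(t) for s in tagged.spans)
    ]
    reconstructed = sorted(
        [t.text for t in covered] + [t.text for t in tagged.unmatched_tokens]
    )
    assert reconstructed == sorted(t.text for t in tokens)


@given(names_from_pool)
@settings(max_examples=200, deadline=None)
def test_removing_brand_rule_never_adds_brand_spans(name):
    rules = _DEMO_RULES_NH
    with_bn = tag_name(name, rules)
    without_bn = tag_name(name, rules.without("BN"))
    n_with = sum(s.term_type == "BN" for s in with_bn.spans)
    n_without = sum(s.term_type == "BN" for s in without_bn.spans)
    assert n_without <= n_with


# --- brute-force oracle ----------------------------------------------

def _oracle_lexicon():
    rows = [
        ("solgar", "BN"), ("gnc", "BN"), ("herb pharm", "BN"),
        ("green tea", "IN"), ("tea", "IN"), ("zinc", "IN"), ("melatonin", "IN"),
        ("hawthorn", "IN"), ("elderberry", "IN"),
        ("powder", "DF"), ("capsule", "DF"), ("spray", "DF"),
        ("leaf", "PLNT"), ("berry", "PLNT"),
        ("extract", "PREP"), ("dried", "PREP"),
        ("lemon", "FLV"), ("energy", "USE"),
        ("with", "STOP"), ("the", "STOP"),
    ]
    return Lexicon([LexiconEntry(s, s, tt, "test") for s, tt in rows])


def brute_force_tag(name, rules):
    """Enumerate every consistent span assignment; return the best one.

    Best = lexicographically maximal per-rule claimed character counts
    in rule order (higher-priority rules claim as much as possible
    first), ties broken toward the leftmost span positions.  This is
    an independent specification of what the greedy claimer computes.
    """
    tokens = tokenize(name)
    cands = []
    for idx, rule in enumerate(rules.rules):
        for c in rule.find(tokens):
            cands.append((idx, rule.term_type, c))
    best_key, best_spans = None, []
    for mask in range(2 ** len(cands)):
        chosen = [cands[k] for k in range(len(cands)) if (mask >> k) & 1]
        used = set()
        ok = True
        for _, _, c in chosen:
            r = set(range(c.i, c.j))
            if used & r:
                ok = False
                break
            used |= r
        if not ok:
            continue
        if not rules.config.multi_ingredient:
            if sum(tt == "IN" for _, tt, _ in chosen) > 1:
                continue
        score = [0] * len(rules.rules)
        for idx, _, c in chosen:
            score[idx] += sum(tokens[k].end - tokens[k].start
                              for k in range(c.i, c.j))
        tie = tuple(sorted((idx, c.i) for idx, _, c in chosen))
        key = (tuple(score), tuple(-i for _, i in tie))
        if best_key is None or key > best_key:
            best_key = key
            best_spans = [
                (tokens[c.i].start, tokens[c.j - 1].end, tt)
                for _, tt, c in chosen
            ]
    return sorted(best_spans)


@given(st.lists(st.sampled_from([
    "Solgar", "GNC", "Herb", "Pharm", "Green", "Tea", "Zinc", "Powder",
    "Leaf", "Extract", "with", "200", "mg", "Lemon",
]), min_size=1, max_size=4).map(" ".join))
@settings(max_examples=150, deadline=None)
def test_greedy_tagger_matches_exhaustive_oracle(name):
    rules = compile_rules(_oracle_lexicon(), RuleConfig(brand_heuristic=False))
    tagged = tag_name(name, rules)
    got = sorted((s.start, s.end, s.term_type) for s in tagged.spans)
    assert got == brute_force_tag(name, rules)
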