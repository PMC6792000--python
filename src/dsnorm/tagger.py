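"""Ordered rule-based span tagging of product names.

A product name is tokenized and rules are applied in a fixed priority
order; each rule may only claim tokens not yet claimed by an earlier
rule.  Brands are searched first, then ingredients, then the remaining
content types, with stop words last, because brands and ingredients have
the most potential to overlap other types.  Within one rule, longer
surface matches win and ties go to the leftmost candidate.

Rules are of three kinds:

* dictionary matchers over the lexicon's surface forms (all types);
* regexes — a strength matcher requiring a number followed by a unit
  (so bare ``mg`` never fires on ``Magnesium``), and a vitamin matcher
  recognizing ``vitamin`` plus a letter designator as an ingredient;
* a toggleable brand heuristic for out-of-lexicon manufacturers: a
  name-initial run of up to three capitalized tokens that precede the
  first token any other rule can match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from itertools import groupby

from .lexicon import Lexicon
from .termtypes import PRIORITY_ORDER, STOP, is_valid_code

__all__ = [
    "Token",
    "Span",
    "MatchedSpan",
    "TaggedName",
    "RuleConfig",
    "Rule",
    "RuleSet",
    "tokenize",
    "compile_rules",
    "tag_name",
    "STRENGTH_UNITS",
]

#: Punctuation stripped from token edges (internal characters such as
#: the apostrophe in "Nature's" or the hyphen in "Non-GMO" are kept).
_STRIP_CHARS = ",.;:!?\"'`()[]{}<>"

#: Recognized strength units (lowercased).  ``%`` and ``billion cfu``
#: are handled specially by the strength matcher.
STRENGTH_UNITS: tuple[str, ...] = (
    "mg", "mcg", "µg", "ug", "g", "kg", "iu", "ml", "l", "%",
)

_UNIT_DISPLAY = {"iu": "IU", "µg": "mcg", "ug": "mcg"}

_NUMBER_RE = re.compile(r"\d{1,3}(?:,\d{3})+(?:\.\d+)?|\d+(?:\.\d+)?")
_UNIT_RE = re.compile("|".join(re.escape(u) for u in STRENGTH_UNITS), re.IGNORECASE)
_ATTACHED_STR_RE = re.compile(
    rf"(?P<num>{_NUMBER_RE.pattern})\s*(?P<unit>{_UNIT_RE.pattern})",
    re.IGNORECASE,
)
_VITAMIN_DESIGNATOR_RE = re.compile(r"(?:b(?:1[0-2]|[1-9])?|d3?|k2?|[ace])", re.IGNORECASE)


def _normalize_quotes(text: str) -> str:
    return text.replace("’", "'").replace("‘", "'")


@dataclass(frozen=True)
class Token:
    """A whitespace-delimited chunk with edge punctuation stripped.

    ``text`` is the original substring at ``[start, end)``; ``norm`` is
    its lowercased, quote-folded form used for matching.
    """

    text: str
    start: int
    end: int
    norm: str


def tokenize(name: str) -> list[Token]:
    """Split on whitespace, strip edge punctuation, keep offsets.

    Chunks that are pure punctuation are dropped.  Offsets index into
    the original string, so ``name[t.start:t.end] == t.text``.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", name):
        start, end = m.start(), m.end()
        chunk = m.group()
        lead = len(chunk) - len(chunk.lstrip(_STRIP_CHARS))
        trail = len(chunk) - len(chunk.rstrip(_STRIP_CHARS))
        start += lead
        end -= trail
        if start >= end:
            continue
        text = name[start:end]
        tokens.append(Token(text, start, end, _normalize_quotes(text).lower()))
    return tokens


@dataclass(frozen=True)
class Span:
    """Character span, 0-based half-open; ``text`` is the covered substring."""

    start: int
    end: int
    text: str


@dataclass(frozen=True)
class MatchedSpan:
    """A span claimed by a rule, with its term type and normalized form."""

    span: Span
    term_type: str
    canonical: str
    rule_id: str

    @property
    def start(self) -> int:
        return self.span.start

    @property
    def end(self) -> int:
        return self.span.end

    @property
    def text(self) -> str:
        return self.span.text

    def covers(self, token: Token) -> bool:
        return self.start <= token.start and token.end <= self.end


@dataclass(frozen=True)
class TaggedName:
    """A product name with its ordered, non-overlapping typed spans.

    ``status`` is ``"full"`` when every token is claimed by some span
    and at least one content (non-stop) span exists, ``"none"`` when no
    content span exists, and ``"partial"`` otherwise.  Stop-word spans
    are recorded but excluded from templates and normalized output.
    """

    name: str
    spans: tuple[MatchedSpan, ...]
    unmatched_tokens: tuple[Token, ...]
    status: str
    name_id: str | None = None

    @property
    def content_spans(self) -> tuple[MatchedSpan, ...]:
        return tuple(s for s in self.spans if s.term_type != STOP)


@dataclass(frozen=True)
class RuleConfig:
    """Toggles changing how rules are compiled and applied.

    ``brand_heuristic`` enables tagging of out-of-lexicon leading
    capitalized tokens as BN.  ``multi_ingredient`` lifts the default
    cap of one ingredient span per name (single-ingredient products are
    the modeled case; the cap avoids spurious extra IN matches).
    """

    brand_heuristic: bool = True
    multi_ingredient: bool = False


@dataclass(frozen=True)
class _Candidate:
    i: int            # first token index
    j: int            # one past last token index
    canonical: str
    rule_id: str
    char_len: int


@dataclass(frozen=True)
class Rule:
    """One matcher: a term type plus a candidate finder."""

    term_type: str
    rule_id: str
    kind: str  # "dict" | "regex"
    surfaces: tuple[tuple[tuple[str, ...], str], ...] = ()  # (words, canonical)

    def find(self, tokens: list[Token]) -> list[_Candidate]:
        if self.kind == "dict":
            return self._find_dict(tokens)
        if self.rule_id == "STR:regex":
            return _find_strength(tokens)
        if self.rule_id == "IN:vitamin":
            return _find_vitamin(tokens)
        raise ValueError(f"unknown rule {self.rule_id!r}")

    def _find_dict(self, tokens: list[Token]) -> list[_Candidate]:
        norms = [t.norm for t in tokens]
        out = []
        for words, canonical in self.surfaces:
            k = len(words)
            for i in range(len(tokens) - k + 1):
                if tuple(norms[i:i + k]) == words:
                    char_len = tokens[i + k - 1].end - tokens[i].start
                    out.append(_Candidate(i, i + k, canonical, self.rule_id, char_len))
        return out


def _find_strength(tokens: list[Token]) -> list[_Candidate]:
    out = []
    n = len(tokens)
    for i, tok in enumerate(tokens):
        num = _NUMBER_RE.fullmatch(tok.norm)
        if num:
            # "5 billion CFU" style counts
            if i + 2 < n and tokens[i + 1].norm == "billion" and tokens[i + 2].norm == "cfu":
                canonical = f"{tok.norm} billion CFU"
                char_len = tokens[i + 2].end - tok.start
                out.append(_Candidate(i, i + 3, canonical, "STR:regex", char_len))
                continue
            # separated unit: "200 IU", "625 MG"
            if i + 1 < n and _UNIT_RE.fullmatch(tokens[i + 1].norm):
                unit = tokens[i + 1].norm
                canonical = f"{tok.norm} {_UNIT_DISPLAY.get(unit, unit)}"
                char_len = tokens[i + 1].end - tok.start
                out.append(_Candidate(i, i + 2, canonical, "STR:regex", char_len))
                continue
        # attached unit: "200mg", "5%"
        m = _ATTACHED_STR_RE.fullmatch(tok.norm)
        if m:
            unit = m.group("unit").lower()
            canonical = f"{m.group('num')} {_UNIT_DISPLAY.get(unit, unit)}"
            out.append(_Candidate(i, i + 1, canonical, "STR:regex", len(tok.text)))
    return out


def _find_vitamin(tokens: list[Token]) -> list[_Candidate]:
    out = []
    for i in range(len(tokens) - 1):
        if tokens[i].norm == "vitamin" and _VITAMIN_DESIGNATOR_RE.fullmatch(tokens[i + 1].norm):
            canonical = f"Vitamin {tokens[i + 1].norm.upper()}"
            char_len = tokens[i + 1].end - tokens[i].start
            out.append(_Candidate(i, i + 2, canonical, "IN:vitamin", char_len))
    return out


@dataclass(frozen=True)
class RuleSet:
    """Ordered rules plus the configuration they were compiled under."""

    rules: tuple[Rule, ...]
    config: RuleConfig = field(default_factory=RuleConfig)

    def without(self, term_type: str) -> "RuleSet":
        """A copy with every rule of *term_type* removed (ablation aid)."""
        return replace(self, rules=tuple(r for r in self.rules if r.term_type != term_type))

    def rule_position(self, term_type: str) -> int:
        for i, r in enumerate(self.rules):
            if r.term_type == term_type:
                return i
        raise KeyError(term_type)


def compile_rules(lexicon: Lexicon, config: RuleConfig | None = None) -> RuleSet:
    """Build the ordered rule set from a lexicon.

    Per term type a dictionary matcher over the lexicon surfaces
    (longest surface first) is emitted; the strength regex and vitamin
    regex are added under their types.  Rules are ordered by the fixed
    priority: BN, IN, STR, DF, DFG, PLNT, PREP, ANM, FLV, POP, CERT,
    TIM, USE, STOP.
    """
    config = config or RuleConfig()
    rules: list[Rule] = []
    for tt in PRIORITY_ORDER:
        if not is_valid_code(tt):  # defensive; PRIORITY_ORDER is fixed
            raise ValueError(f"unknown term type {tt!r}")
        surfaces = tuple(
            (e.words, e.canonical) for e in lexicon.entries_for(tt)
        )
        if surfaces:
            rules.append(Rule(tt, f"{tt}:dict", "dict", surfaces))
        if tt == "IN":
            rules.append(Rule("IN", "IN:vitamin", "regex"))
        if tt == "STR":
            rules.append(Rule("STR", "STR:regex", "regex"))
    return RuleSet(tuple(rules), config)


def _claim(
    cands: list[_Candidate],
    free: list[bool],
    budget: int | None,
) -> list[_Candidate]:
    """Greedily claim non-conflicting candidates, longest first, leftmost on ties."""
    cands = sorted(cands, key=lambda c: (-(c.j - c.i), -c.char_len, c.i))
    claimed = []
    for c in cands:
        if budget is not None and len(claimed) >= budget:
            break
        if all(free[k] for k in range(c.i, c.j)):
            for k in range(c.i, c.j):
                free[k] = False
            claimed.append(c)
    return claimed


def _is_capitalized(token: Token) -> bool:
    return token.text[:1].isupper()


def _heuristic_brand_run(
    tokens: list[Token], free: list[bool], rules: RuleSet
) -> _Candidate | None:
    """Name-initial run of capitalized, otherwise-unmatchable tokens as BN.

    The run starts at the first token, extends over at most 3 capitalized
    tokens, and must stop before the first token any non-brand rule can
    match on the fresh name.
    """
    if not tokens or not free[0]:
        return None
    first_other = len(tokens)
    for rule in rules.rules:
        if rule.term_type == "BN":
            continue
        for c in rule.find(tokens):
            first_other = min(first_other, c.i)
    j = 0
    while j < min(3, first_other) and free[j] and _is_capitalized(tokens[j]):
        j += 1
    if j == 0:
        return None
    char_len = tokens[j - 1].end - tokens[0].start
    return _Candidate(0, j, "", "BN:heuristic", char_len)


def tag_name(name: str, rules: RuleSet) -> TaggedName:
    """Tag one product name, returning its typed spans and match status.

    Any string is taggable; the worst case is an output with no spans
    and status ``"none"``.
    """
    tokens = tokenize(name)
    free = [True] * len(tokens)
    claimed: list[tuple[str, _Candidate]] = []

    def run_heuristic() -> None:
        h = _heuristic_brand_run(tokens, free, rules)
        if h is not None:
            for k in range(h.i, h.j):
                free[k] = False
            claimed.append(("BN", h))

    # The heuristic fires at BN's priority position: right after the BN
    # dictionary rule, or first of all when no BN rule is present.
    if rules.config.brand_heuristic and not any(r.term_type == "BN" for r in rules.rules):
        run_heuristic()

    for tt, group in groupby(rules.rules, key=lambda r: r.term_type):
        cands = [c for r in group for c in r.find(tokens)]
        budget = 1 if tt == "IN" and not rules.config.multi_ingredient else None
        got = _claim(cands, free, budget)
        claimed.extend((tt, c) for c in got)
        if tt == "BN" and rules.config.brand_heuristic:
            run_heuristic()

    spans = []
    for tt, c in claimed:
        start = tokens[c.i].start
        end = tokens[c.j - 1].end
        text = name[start:end]
        canonical = c.canonical or text
        spans.append(MatchedSpan(Span(start, end, text), tt, canonical, c.rule_id))
    spans.sort(key=lambda s: s.start)

    unmatched = tuple(t for t, f in zip(tokens, free) if f)
    content = [s for s in spans if s.term_type != STOP]
    if not content:
        status = "none"
    elif not unmatched:
        status = "full"
    else:
        status = "partial"
    return TaggedName(name, tuple(spans), unmatched, status)
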