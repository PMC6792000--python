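"""Term-type taxonomy for supplement product-name components.

Product names are decomposed into typed components in the style of the
RxNorm drug-name model: an ingredient (IN), a brand (BN), a strength
(STR), a dose form (DF) and so on.  Fourteen codes exist; the stop-word
code STOP marks uninformative tokens and is excluded from the derived
templates, leaving 13 content types.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TermType:
    """A code classifying a matched span of a product name.

    Attributes
    ----------
    code:
        Upper-case abbreviation, e.g. ``"IN"``.
    description:
        Human-readable meaning of the code.
    pattern_source:
        Provenance of the keywords/rules that recognize this type
        (terminology name, manual annotation, or regex rules).
    """

    code: str
    description: str
    pattern_source: str


_TERM_TYPES = (
    TermType("ANM", "Animal source: the part of an animal from which the ingredient is derived", "TGA"),
    TermType("BN", "Brand name: manufacturer's name", "annotation, rules"),
    TermType("CERT", "Certification: official certifications claimed by the product", "TGA"),
    TermType("USE", "Claim or use: purported use of the supplement", "annotation"),
    TermType("DF", "Dose form: the physical form of the product", "TGA, RxNorm"),
    TermType("DFG", "Dose form group: dose forms related by route of administration", "TGA, RxNorm"),
    TermType("FLV", "Flavor of the supplement", "annotation"),
    TermType("IN", "Ingredient: name of the dietary supplement ingredient", "iDISK, rules"),
    TermType("PLNT", "Plant source: the part of a plant from which the ingredient is derived", "TGA"),
    TermType("POP", "Demographic or population the product is intended for", "TGA"),
    TermType("PREP", "Preparation: how an ingredient is prepared", "TGA"),
    TermType("STOP", "Stop word: uninformative words excluded from the normalized form", "annotation"),
    TermType("STR", "Strength: the quantity of the ingredient in a product", "TGA"),
    TermType("TIM", "Time of use: when the product is intended to be used", "TGA"),
)

#: All 14 term types, keyed by code.
TERM_TYPES: dict[str, TermType] = {t.code: t for t in _TERM_TYPES}

#: The stop-word code, excluded from templates and normalized output.
STOP = "STOP"

#: Canonical ordering of the 13 content codes.  Templates are presented
#: in this order so that equal multisets of codes yield equal templates,
#: and so that the composite RxNorm term types (SBDC = BN IN STR, SCD =
#: IN STR DF, ...) read off directly.
CANONICAL_ORDER: tuple[str, ...] = (
    "BN", "IN", "STR", "DF", "DFG", "PLNT", "PREP",
    "ANM", "FLV", "POP", "CERT", "TIM", "USE",
)

#: Priority in which matchers claim spans: closed-class, specific
#: patterns first (brands before ingredients before everything else,
#: since those overlap other types the most), the open-ended USE type
#: last among content types, and STOP last of all so content rules get
#: first claim on every token.
PRIORITY_ORDER: tuple[str, ...] = CANONICAL_ORDER + (STOP,)

_CANONICAL_RANK = {code: i for i, code in enumerate(CANONICAL_ORDER)}


def is_valid_code(code: str) -> bool:
    """Return True if *code* is one of the 14 term-type codes."""
    return code in TERM_TYPES


def canonical_rank(code: str) -> int:
    """Sort key placing content codes in canonical template order."""
    return _CANONICAL_RANK[code]
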