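"""Seeded generator of supplement-style product names with gold spans.

Real supplement label corpora cannot be redistributed, so every part of
the pipeline is exercised on synthetic names built to the same plan a
label generator would follow: a brand prefix, one ingredient, and
optional strength / dose-form / plant-part / flavor / claim suffixes,
with stop words sprinkled between slots and an adjustable fraction of
out-of-lexicon ("OOV") brands emulating manufacturers missing from the
brand list.  Each record carries exact gold spans for the slots drawn
from the lexicon, so tagging can be scored against a known truth.

Default template weights follow the empirically dominant structures of
single-ingredient supplement names — BN IN STR (32.0%), BN IN (21.3%),
BN IN DF (3.4%), BN IN STR DF (3.0%), BN IN PLNT (1.9%) — with the
remaining mass split between BN IN USE and BN IN FLV so that templates
without an RxNorm counterpart are exercised too.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .evaluation import GoldAnnotation
from .lexicon import Lexicon, load_demo_lexicon
from .templates import Template
from .termtypes import STOP

__all__ = [
    "GeneratorConfig",
    "SyntheticRecord",
    "DEFAULT_TEMPLATE_WEIGHTS",
    "generate",
    "stratified_split",
]

#: Weights of the name structures the generator samples from.
DEFAULT_TEMPLATE_WEIGHTS: dict[Template, float] = {
    Template.parse("BN IN STR"): 0.320,
    Template.parse("BN IN"): 0.213,
    Template.parse("BN IN DF"): 0.034,
    Template.parse("BN IN STR DF"): 0.030,
    Template.parse("BN IN PLNT"): 0.019,
    Template.parse("BN IN USE"): 0.192,
    Template.parse("BN IN FLV"): 0.192,
}

#: Units the strength sampler draws from (display forms).
SYNTH_STRENGTH_UNITS: tuple[str, ...] = ("mg", "mcg", "g", "IU", "ml")

_OOV_SYLLABLES = (
    "zor", "vex", "nux", "qar", "blin", "trud", "phax", "grom",
    "lyn", "dex", "vit", "max", "pur", "kor", "zen", "flux",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus.

    ``stop_insert_prob`` is the chance of inserting a stop word between
    two slots; ``oov_brand_prob`` the chance that a name's brand is an
    invented token absent from the lexicon (OOV brands get no gold
    span: the gold records only what dictionary knowledge could have
    found).  Defaults of 0.1 each keep most names fully resolvable
    while exercising partial matches, roughly like a held-out label
    set facing an incomplete brand list.
    """

    n: int = 1000
    seed: int = 0
    template_weights: dict[Template, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE_WEIGHTS)
    )
    stop_insert_prob: float = 0.1
    oov_brand_prob: float = 0.1
    lexicon: Lexicon | None = None
    strata: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        total = sum(self.template_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"template weights must sum to 1, got {total}")
        for p in (self.stop_insert_prob, self.oov_brand_prob,
                  *self.template_weights.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass(frozen=True)
class SyntheticRecord:
    """A generated name, its gold spans, true structure, and stratum."""

    name_id: str
    name: str
    gold: GoldAnnotation
    true_template: Template
    stratum: str


def _oov_brand(rng: random.Random, lexicon: Lexicon) -> str:
    known = {e.surface for e in lexicon.entries}
    while True:
        word = "".join(rng.choice(_OOV_SYLLABLES) for _ in range(2)).capitalize()
        if word.lower() not in known:
            return word


def generate(config: GeneratorConfig) -> list[SyntheticRecord]:
    """Generate ``config.n`` records, deterministically in the seed.

    Each record samples a template by weight, fills every slot from the
    lexicon (strengths from an integer-times-unit sampler), optionally
    prepends/intersperses stop words and swaps the brand for an OOV
    token, and records exact character-offset gold spans with label 1.

    Raises ``ValueError`` when a template references a term type with
    no lexicon entries to draw from.
    """
    lexicon = config.lexicon if config.lexicon is not None else load_demo_lexicon()
    rng = random.Random(config.seed)
    templates = list(config.template_weights)
    weights = [config.template_weights[t] for t in templates]

    needed = {tt for t in templates for tt in t.types if tt != "STR"}
    pools = {tt: lexicon.base_entries_for(tt) for tt in needed}
    empty = sorted(tt for tt, pool in pools.items() if not pool)
    if empty:
        raise ValueError(
            "template weights reference term type(s) with an empty lexicon "
            "section: " + ", ".join(empty)
        )
    stop_pool = lexicon.base_entries_for(STOP)
    if config.stop_insert_prob > 0 and not stop_pool:
        raise ValueError("stop_insert_prob > 0 but the lexicon has no stop words")

    records = []
    for i in range(config.n):
        template = rng.choices(templates, weights=weights, k=1)[0]
        pieces: list[tuple[str, str | None]] = []  # (text, term_type or None)
        for slot_idx, tt in enumerate(template.types):
            if slot_idx > 0 and rng.random() < config.stop_insert_prob:
                pieces.append((rng.choice(stop_pool).surface, None))
            if tt == "STR":
                text = f"{rng.randint(5, 2000)} {rng.choice(SYNTH_STRENGTH_UNITS)}"
                pieces.append((text, "STR"))
            elif tt == "BN" and rng.random() < config.oov_brand_prob:
                pieces.append((_oov_brand(rng, lexicon), None))
            else:
                entry = rng.choice(pools[tt])
                pieces.append((entry.canonical, tt))

        labels: dict[tuple[int, int, str], int] = {}
        parts = []
        offset = 0
        for text, tt in pieces:
            if parts:
                offset += 1  # joining space
            if tt is not None:
                labels[(offset, offset + len(text), tt)] = 1
            parts.append(text)
            offset += len(text)
        name = " ".join(parts)
        name_id = f"synth-{i:06d}"
        stratum = " ".join(template.types[:2])
        records.append(
            SyntheticRecord(
                name_id, name, GoldAnnotation(name_id, labels), template, stratum
            )
        )
    return records


def stratified_split(
    records: list[SyntheticRecord], fraction: float, seed: int = 0
) -> tuple[list[SyntheticRecord], list[SyntheticRecord]]:
    """Split records into (development, evaluation) sets per stratum.

    Within each stratum, round(fraction * size) records go to the
    development set after a seeded shuffle; the rest go to evaluation.
    The two sets partition the input.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = random.Random(seed)
    by_stratum: dict[str, list[SyntheticRecord]] = {}
    for r in records:
        by_stratum.setdefault(r.stratum, []).append(r)
    dev, holdout = [], []
    for stratum in sorted(by_stratum):
        group = by_stratum[stratum][:]
        rng.shuffle(group)
        k = math.floor(len(group) * fraction + 0.5)
        dev.extend(group[:k])
        holdout.extend(group[k:])
    return dev, holdout
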