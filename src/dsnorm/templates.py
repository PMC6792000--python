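"""Normalization templates and their mapping onto RxNorm term types.

A template is the ordered list of term-type codes summarizing a tagged
name's structure — ``BN IN STR`` for "Bronson Laboratories Vitamin E
200 IU".  Stop words are dropped, and codes are reordered into the
canonical order so that equal multisets of codes always yield the same
template regardless of surface word order.  Templates whose structure
matches an RxNorm composite term type (SBDC, SCD, ...) map onto it;
others (notably ``BN IN``, the second most common structure in
supplement names) have no RxNorm counterpart.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .tagger import TaggedName
from .termtypes import STOP, canonical_rank, is_valid_code

__all__ = [
    "Template",
    "RxNormMap",
    "derive_template",
    "map_to_rxnorm",
    "normalize_name",
    "template_frequencies",
    "load_rxnorm_map",
]


@dataclass(frozen=True)
class Template:
    """An ordered sequence of content term-type codes (STOP excluded).

    Duplicate codes are preserved adjacently (two ingredients under the
    multi-ingredient extension give ``IN IN``).
    """

    types: tuple[str, ...]

    def __post_init__(self) -> None:
        for code in self.types:
            if not is_valid_code(code) or code == STOP:
                raise ValueError(f"invalid template code {code!r}")

    @classmethod
    def of(cls, codes: Iterable[str]) -> "Template":
        """Build a template from codes, dropping STOP and order-normalizing."""
        kept = [c for c in codes if c != STOP]
        kept.sort(key=canonical_rank)  # stable: duplicates stay adjacent
        return cls(tuple(kept))

    @classmethod
    def parse(cls, text: str) -> "Template":
        """Parse a space-separated code list such as ``"BN IN STR"``."""
        return cls.of(text.split())

    def __str__(self) -> str:
        return " ".join(self.types)

    def __bool__(self) -> bool:
        return bool(self.types)


def derive_template(tagged: TaggedName) -> Template:
    """The template of a tagged name: its span types, STOP dropped,
    reordered canonically.  A name with no content spans yields the
    empty template."""
    return Template.of(s.term_type for s in tagged.content_spans)


def normalize_name(tagged: TaggedName) -> str:
    """Join the canonical forms of content spans in template order.

    Spans are ordered by the canonical rank of their type (ties by
    surface position), so the normalized string always reads brand,
    ingredient, strength, dose form, ...  A status-``none`` name yields
    the empty string.
    """
    spans = sorted(
        tagged.content_spans,
        key=lambda s: (canonical_rank(s.term_type), s.start),
    )
    return " ".join(s.canonical for s in spans)


@dataclass(frozen=True)
class RxNormMap:
    """Exact mapping from templates to RxNorm term-type codes.

    Covers the ten codes applicable to single-ingredient supplement
    names: IN, SCDC, SCDF, SCDG, SCD, BN, SBDC, SBDF, SBDG, SBD.  Pack
    and multi-ingredient codes (GPCK, BPCK, MIN, PIN) do not apply.
    """

    entries: Mapping[Template, str]

    def lookup(self, template: Template) -> str | None:
        return self.entries.get(template)


def _rxnorm_map_path() -> Path:
    return Path(__file__).parent / "data" / "rxnorm_templates.tsv"


def load_rxnorm_map(path: str | Path | None = None) -> RxNormMap:
    """Load the template → RxNorm code table (bundled copy by default)."""
    path = Path(path) if path else _rxnorm_map_path()
    entries: dict[Template, str] = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            template_text, code = line.split("\t")
            entries[Template.parse(template_text)] = code
    return RxNormMap(entries)


_DEFAULT_MAP: RxNormMap | None = None


def _default_map() -> RxNormMap:
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = load_rxnorm_map()
    return _DEFAULT_MAP


def map_to_rxnorm(template: Template, rxmap: RxNormMap | None = None) -> str | None:
    """The RxNorm term type matching *template*, or None when absent."""
    return (rxmap or _default_map()).lookup(template)


def template_frequencies(
    corpus: Iterable[TaggedName],
) -> dict[Template, tuple[int, float]]:
    """Count templates over the fully matched names of a corpus.

    Returns template → (count, fraction); fractions are relative to the
    number of fully matched names and sum to 1 (empty mapping for a
    corpus without full matches).
    """
    counts: Counter[Template] = Counter()
    for tagged in corpus:
        if tagged.status == "full":
            counts[derive_template(tagged)] += 1
    total = sum(counts.values())
    return {
        t: (c, c / total)
        for t, c in sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    }


def write_frequency_report(
    frequencies: Mapping[Template, tuple[int, float]], path: str | Path
) -> None:
    """Write a template frequency table as TSV (template, count, fraction)."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["template", "count", "fraction"])
        for template, (count, fraction) in frequencies.items():
            writer.writerow([str(template), count, f"{fraction:.6f}"])
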