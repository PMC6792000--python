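"""Keyword lexicons driving dictionary-based span matching.

A :class:`Lexicon` maps surface forms (how a keyword may appear in a
product name) to canonical forms, per term type.  Lexicons are loaded
from hand-editable TSV (4 columns: surface, canonical, term_type,
source; ``#`` comments) or from a flat JSON array of objects with the
same keys.  Matching is case-insensitive: surfaces are stored
lowercased, canonicals keep their original casing.

Variant expansion adds plural forms (``+s``, ``+es`` after s/x/z/ch/sh)
and entries from a small curated abbreviation table (``cap``/``caps``
for ``capsule`` and the like); variants inherit the canonical form of
the base entry, so normalized output always uses the preferred form.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from .termtypes import TERM_TYPES, is_valid_code

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "load_lexicon",
    "save_lexicon",
    "expand_variants",
    "collision_report",
    "demo_lexicon_path",
    "load_demo_lexicon",
]

#: Source suffix marking rule-generated variant entries.  Expansion is a
#: no-op on entries carrying it, which makes expanding a lexicon
#: idempotent.
VARIANT_TAG = "+variant"

#: Curated abbreviation table: base surface -> abbreviated surfaces.
#: These are added alongside (not instead of) plural variants.
ABBREVIATIONS: dict[str, tuple[str, ...]] = {
    "capsule": ("cap", "caps"),
    "tablet": ("tab", "tabs"),
    "ounce": ("oz",),
    "teaspoon": ("tsp",),
    "tablespoon": ("tbsp",),
    "pound": ("lb", "lbs"),
}


class LexiconError(ValueError):
    """Raised for malformed lexicon files or invalid entries."""


def _normalize_quotes(text: str) -> str:
    # Curly apostrophes/quotes on product labels fold to ASCII so the
    # same keyword matches either spelling.
    return text.replace("’", "'").replace("‘", "'")


@dataclass(frozen=True)
class LexiconEntry:
    """One keyword: a surface form, its canonical form, and its type."""

    surface: str
    canonical: str
    term_type: str
    source: str = ""

    def __post_init__(self) -> None:
        surface = _normalize_quotes(self.surface).strip().lower()
        if not surface:
            raise LexiconError("lexicon entry has an empty surface form")
        object.__setattr__(self, "surface", surface)
        canonical = (self.canonical or "").strip()
        if not canonical:
            canonical = self.surface
        object.__setattr__(self, "canonical", canonical)
        if not is_valid_code(self.term_type):
            raise LexiconError(
                f"unknown term-type code {self.term_type!r} "
                f"(expected one of {sorted(TERM_TYPES)})"
            )

    @property
    def is_variant(self) -> bool:
        return self.source.endswith(VARIANT_TAG)

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(self.surface.split())


def _pluralize(surface: str) -> str:
    if surface.endswith(("s", "x", "z", "ch", "sh")):
        return surface + "es"
    return surface + "s"


def expand_variants(entry: LexiconEntry) -> list[LexiconEntry]:
    """Return *entry* plus its rule-generated variants.

    Variants are the plural form and any curated abbreviations (with
    their plurals); all share the original entry's canonical form and
    term type.  Entries that are themselves variants are returned
    unchanged, so expansion is idempotent at the lexicon level.
    """
    if entry.is_variant:
        return [entry]
    # Stop words and possessives ("children's") have no useful plural.
    if entry.term_type == "STOP" or entry.surface.endswith("'s"):
        return [entry]
    variant_source = entry.source + VARIANT_TAG
    surfaces = [_pluralize(entry.surface)]
    for abbr in ABBREVIATIONS.get(entry.surface, ()):
        surfaces.append(abbr)
        if not abbr.endswith("s"):
            surfaces.append(_pluralize(abbr))
    out = [entry]
    seen = {entry.surface}
    for s in surfaces:
        if s not in seen:
            seen.add(s)
            out.append(
                LexiconEntry(s, entry.canonical, entry.term_type, variant_source)
            )
    return out


class Lexicon:
    """A validated collection of keyword entries with per-type indexes.

    Duplicate (surface, term_type) pairs are dropped, first occurrence
    wins — base entries are inserted before their variants, so a
    hand-listed form always beats a generated one.
    """

    def __init__(self, entries: list[LexiconEntry] | None = None):
        self._by_key: dict[tuple[str, str], LexiconEntry] = {}
        for e in entries or []:
            self.add(e)

    def add(self, entry: LexiconEntry) -> None:
        key = (entry.surface, entry.term_type)
        self._by_key.setdefault(key, entry)

    @property
    def entries(self) -> list[LexiconEntry]:
        return list(self._by_key.values())

    def __len__(self) -> int:
        return len(self._by_key)

    def get(self, term_type: str, surface: str) -> LexiconEntry | None:
        return self._by_key.get((surface.lower(), term_type))

    def entries_for(self, term_type: str) -> list[LexiconEntry]:
        """Entries of one type, longest surface first (words, then chars)."""
        out = [e for e in self._by_key.values() if e.term_type == term_type]
        out.sort(key=lambda e: (-len(e.words), -len(e.surface), e.surface))
        return out

    def base_entries_for(self, term_type: str) -> list[LexiconEntry]:
        """Hand-listed (non-variant) entries of one type, in insertion order."""
        return [
            e for e in self._by_key.values()
            if e.term_type == term_type and not e.is_variant
        ]

    def term_types(self) -> set[str]:
        return {e.term_type for e in self._by_key.values()}

    def expanded(self) -> "Lexicon":
        """A new lexicon with variant expansion applied to every entry."""
        out = Lexicon()
        for e in self._by_key.values():
            out.add(e)
        for e in self._by_key.values():
            for v in expand_variants(e)[1:]:
                out.add(v)
        return out

    def merged(self, other: "Lexicon") -> "Lexicon":
        return Lexicon(self.entries + other.entries)


def collision_report(lexicon: Lexicon) -> dict[str, set[str]]:
    """Map each surface registered under two or more term types to those types.

    Polysemous keywords (``"heart"`` as an animal part vs. a health
    claim) are the main source of tagging ambiguity; this report makes
    them auditable.  Output content does not depend on insertion order.
    """
    by_surface: dict[str, set[str]] = defaultdict(set)
    for e in lexicon.entries:
        by_surface[e.surface].add(e.term_type)
    return {s: types for s, types in by_surface.items() if len(types) >= 2}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "tsv"


def load_lexicon(path: str | Path, fmt: str | None = None, expand: bool = True) -> Lexicon:
    """Load a lexicon from TSV or JSON.

    Parameters
    ----------
    path:
        File to read.  Format is inferred from the extension unless
        *fmt* (``"tsv"`` or ``"json"``) is given.
    expand:
        Apply variant expansion after loading (default).

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    LexiconError
        For malformed rows (with line number) or unknown term-type
        codes (listing every offending code).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"lexicon file not found: {path}")
    fmt = _infer_format(path, fmt)
    rows: list[tuple[int, str, str, str, str]] = []
    if fmt == "json":
        try:
            data = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise LexiconError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(data, list):
            raise LexiconError(f"{path}: expected a JSON array of objects")
        for i, obj in enumerate(data):
            if not isinstance(obj, dict) or "surface" not in obj or "term_type" not in obj:
                raise LexiconError(
                    f"{path}: element {i}: expected an object with "
                    "'surface' and 'term_type' keys"
                )
            rows.append(
                (i, obj["surface"], obj.get("canonical", ""),
                 obj["term_type"], obj.get("source", ""))
            )
    elif fmt == "tsv":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise LexiconError(
                        f"{path}:{lineno}: expected 4 tab-separated fields "
                        f"(surface, canonical, term_type, source), got {len(fields)}"
                    )
                rows.append((lineno, *fields))
    else:
        raise LexiconError(f"unknown lexicon format {fmt!r}")

    bad_codes = sorted({tt for _, _, _, tt, _ in rows if not is_valid_code(tt)})
    if bad_codes:
        raise LexiconError(
            f"{path}: unknown term-type code(s): {', '.join(bad_codes)}"
        )
    entries = []
    for lineno, surface, canonical, term_type, source in rows:
        try:
            entries.append(LexiconEntry(surface, canonical, term_type, source))
        except LexiconError as exc:
            raise LexiconError(f"{path}:{lineno}: {exc}") from exc
    lex = Lexicon(entries)
    return lex.expanded() if expand else lex


def save_lexicon(lexicon: Lexicon, path: str | Path, fmt: str | None = None) -> None:
    """Write a lexicon back to TSV or JSON (inverse of :func:`load_lexicon`)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        data = [
            {"surface": e.surface, "canonical": e.canonical,
             "term_type": e.term_type, "source": e.source}
            for e in lexicon.entries
        ]
        path.write_text(json.dumps(data, indent=1, ensure_ascii=False) + "\n",
                        encoding="utf-8")
    elif fmt == "tsv":
        lines = ["# surface\tcanonical\tterm_type\tsource"]
        lines += [
            f"{e.surface}\t{e.canonical}\t{e.term_type}\t{e.source}"
            for e in lexicon.entries
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise LexiconError(f"unknown lexicon format {fmt!r}")


def demo_lexicon_path() -> Path:
    """Path of the bundled demonstration lexicon."""
    return Path(__file__).parent / "data" / "demo_lexicon.tsv"


def load_demo_lexicon(expand: bool = True) -> Lexicon:
    """Load the bundled demonstration lexicon shipped with the package."""
    return load_lexicon(demo_lexicon_path(), expand=expand)
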