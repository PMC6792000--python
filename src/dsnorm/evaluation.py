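"""Coverage and accuracy metrics for tagged product names.

Coverage partitions a corpus by match status (full / partial / none).
Accuracy follows a token-level scheme driven by span annotations: each
predicted (span, term type) pair carries a binary correctness label;
every token inside a labeled span inherits that label, and every token
matched by no span is implicitly wrong (label 0).  The accuracy of one
name is the mean of its token labels,

    accuracy(n) = (1 / |T(n)|) * sum over t in T(n) of l(t)

where T(n) are the name's tokens and l(t) in {0, 1}.  Corpus accuracy
is the unweighted mean over names, reported overall and restricted to
the fully matched and partially matched strata.  Tokens claimed by a
stop-word span are excluded from T(n): stop words are removed from
names before matching and carry no information about tagging quality.

Gold annotations are read from TSV with columns (name_id, start, end,
term_type, label), using 0-based half-open character offsets — the same
convention the tagger emits, so predictions are auditable against gold
line by line.
"""

from __future__ import annotations

import csv
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .tagger import TaggedName, tokenize
from .termtypes import STOP

__all__ = [
    "GoldAnnotation",
    "EvaluationError",
    "CoverageFractions",
    "StratumAccuracy",
    "EvaluationReport",
    "coverage",
    "name_accuracy",
    "corpus_accuracy",
    "load_gold",
    "save_gold",
]


class EvaluationError(ValueError):
    """Raised for undefined metrics or prediction/gold mismatches."""


@dataclass(frozen=True)
class GoldAnnotation:
    """Binary correctness labels for one name's (span, term type) pairs.

    ``labels`` maps (start, end, term_type) to 0 or 1.  A predicted
    span absent from the mapping is treated as incorrect (0), as is any
    unmatched token.
    """

    name_id: str
    labels: Mapping[tuple[int, int, str], int]

    def __post_init__(self) -> None:
        for key, value in self.labels.items():
            if value not in (0, 1):
                raise EvaluationError(
                    f"{self.name_id}: label for {key} must be 0 or 1, got {value!r}"
                )

    def label_for(self, start: int, end: int, term_type: str) -> int:
        return self.labels.get((start, end, term_type), 0)


@dataclass(frozen=True)
class CoverageFractions:
    full: float
    partial: float
    none: float

    def as_dict(self) -> dict[str, float]:
        return {"full": self.full, "partial": self.partial, "none": self.none}


@dataclass(frozen=True)
class StratumAccuracy:
    """Metrics restricted to one coverage stratum."""

    n_names: int
    name_accuracy: float | None  # None when the stratum is empty
    per_type_accuracy: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class EvaluationReport:
    """Coverage partition plus overall and per-stratum accuracies."""

    coverage: CoverageFractions
    name_accuracy: float
    per_type_accuracy: dict[str, float]
    strata: dict[str, StratumAccuracy]
    n_names: int

    def as_dict(self) -> dict:
        return {
            "n_names": self.n_names,
            "coverage": self.coverage.as_dict(),
            "name_accuracy": self.name_accuracy,
            "per_type_accuracy": dict(self.per_type_accuracy),
            "strata": {
                key: {
                    "n_names": s.n_names,
                    "name_accuracy": s.name_accuracy,
                    "per_type_accuracy": dict(s.per_type_accuracy),
                }
                for key, s in self.strata.items()
            },
        }

    def accuracy_rows(self) -> list[tuple[str, int, float | None]]:
        """Accuracy table rows: overall, full-only, partial-only."""
        return [
            ("Full + Partial + None", self.n_names, self.name_accuracy),
            ("Full match only", self.strata["full"].n_names,
             self.strata["full"].name_accuracy),
            ("Partial match only", self.strata["partial"].n_names,
             self.strata["partial"].name_accuracy),
        ]

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.as_dict(), indent=1) + "\n", encoding="utf-8"
        )

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["section", "key", "n", "value"])
            for key, value in self.coverage.as_dict().items():
                writer.writerow(["coverage", key, self.n_names, f"{value:.6f}"])
            for label, n, acc in self.accuracy_rows():
                writer.writerow(
                    ["accuracy", label, n, "" if acc is None else f"{acc:.6f}"]
                )
            for tt, acc in sorted(self.per_type_accuracy.items()):
                writer.writerow(["per_type_accuracy", tt, "", f"{acc:.6f}"])


def coverage(corpus: Sequence[TaggedName]) -> CoverageFractions:
    """Fractions of fully / partially / un-matched names in a corpus.

    The three fractions share the corpus size as denominator and sum
    to 1.  An empty corpus has no defined coverage and raises.
    """
    if not corpus:
        raise EvaluationError("coverage is undefined for an empty corpus")
    n = len(corpus)
    counts = {"full": 0, "partial": 0, "none": 0}
    for tagged in corpus:
        counts[tagged.status] += 1
    return CoverageFractions(
        counts["full"] / n, counts["partial"] / n, counts["none"] / n
    )


def _content_tokens(tagged: TaggedName):
    stop_spans = [s for s in tagged.spans if s.term_type == STOP]
    return [
        t for t in tokenize(tagged.name)
        if not any(s.covers(t) for s in stop_spans)
    ]


def name_accuracy(tagged: TaggedName, gold: GoldAnnotation) -> float:
    """Token-label mean for one name.

    Each token inherits the gold label of the predicted span covering
    it; tokens covered by no span count 0.  Raises for a name with no
    tokens, where the mean is undefined.
    """
    if not tokenize(tagged.name):
        raise EvaluationError("accuracy is undefined for a zero-token name")
    tokens = _content_tokens(tagged)
    if not tokens:
        # Name consists solely of stop words: no content to score.
        return 0.0
    total = 0
    for token in tokens:
        for span in tagged.content_spans:
            if span.covers(token):
                total += gold.label_for(span.start, span.end, span.term_type)
                break
    return total / len(tokens)


def corpus_accuracy(
    corpus: Sequence[TaggedName],
    gold: Mapping[str, GoldAnnotation],
) -> EvaluationReport:
    """Evaluate a tagged corpus against gold span labels.

    The overall accuracy is the unweighted mean of per-name accuracies
    over all names, including status-none ones.  Per-term-type accuracy
    is the mean label of predicted spans of that type, computed over
    fully and partially matched names only (status-none names have no
    spans to score).  Raises when gold is missing for any name, listing
    the offending ids.
    """
    missing = [t.name_id or t.name for t in corpus
               if (t.name_id or t.name) not in gold]
    if missing:
        raise EvaluationError(
            "missing gold annotations for: " + ", ".join(map(str, missing[:10]))
        )
    if not corpus:
        raise EvaluationError("accuracy is undefined for an empty corpus")

    per_name: dict[str, list[float]] = {"full": [], "partial": [], "none": []}
    type_labels: dict[str, list[int]] = defaultdict(list)
    type_labels_by_stratum: dict[str, dict[str, list[int]]] = {
        "full": defaultdict(list), "partial": defaultdict(list)
    }
    for tagged in corpus:
        g = gold[tagged.name_id or tagged.name]
        per_name[tagged.status].append(name_accuracy(tagged, g))
        if tagged.status in ("full", "partial"):
            for span in tagged.content_spans:
                label = g.label_for(span.start, span.end, span.term_type)
                type_labels[span.term_type].append(label)
                type_labels_by_stratum[tagged.status][span.term_type].append(label)

    all_acc = [a for accs in per_name.values() for a in accs]
    overall = sum(all_acc) / len(all_acc)
    strata = {}
    for key in ("full", "partial", "none"):
        accs = per_name[key]
        per_type = {
            tt: sum(ls) / len(ls)
            for tt, ls in type_labels_by_stratum.get(key, {}).items()
        }
        strata[key] = StratumAccuracy(
            len(accs), sum(accs) / len(accs) if accs else None, per_type
        )
    per_type_overall = {tt: sum(ls) / len(ls) for tt, ls in type_labels.items()}
    cov = coverage(corpus)
    return EvaluationReport(cov, overall, per_type_overall, strata, len(corpus))


def load_gold(path: str | Path) -> dict[str, GoldAnnotation]:
    """Read gold annotations (TSV: name_id, start, end, term_type, label)."""
    path = Path(path)
    rows: dict[str, dict[tuple[int, int, str], int]] = defaultdict(dict)
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise EvaluationError(
                    f"{path}:{lineno}: expected 5 tab-separated fields "
                    f"(name_id, start, end, term_type, label), got {len(fields)}"
                )
            name_id, start, end, term_type, label = fields
            try:
                rows[name_id][(int(start), int(end), term_type)] = int(label)
            except ValueError as exc:
                raise EvaluationError(f"{path}:{lineno}: {exc}") from exc
    return {nid: GoldAnnotation(nid, labels) for nid, labels in rows.items()}


def save_gold(gold: Iterable[GoldAnnotation], path: str | Path) -> None:
    """Write gold annotations in the TSV dialect :func:`load_gold` reads."""
    lines = ["# name_id\tstart\tend\tterm_type\tlabel"]
    for g in gold:
        for (start, end, term_type), label in sorted(g.labels.items()):
            lines.append(f"{g.name_id}\t{start}\t{end}\t{term_type}\t{label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
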