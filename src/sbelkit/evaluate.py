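"""Multi-level statement scoring and round-trip conversion-loss measurement.

Extracted (or reconstructed) BEL statements are scored against gold
statements at seven levels, from entity-only matching up to full-statement
matching:

Term        entity (namespace:id) sets
FS          function-type occurrence sets (relaxed Function)
Function    (function type, entity) pairs
RS          (subject entity, object entity) pairs, relation type and
            functions ignored (relaxed Relation)
Relation    (subject entity, base relation, object entity) triples,
            functions ignored
State(REL)  statement strings with all functions stripped from the
            prediction, gold statements as written
State(MRG)  full canonical statement strings

Counts are micro-averaged across the corpus with per-sentence grouping, so a
unit predicted in the wrong sentence earns no credit. The round-trip loss of
the SBEL intermediate representation is the P/R/F1 deficit of
BEL -> SBEL -> BEL reconstruction against the original statements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .convert import convert_corpus, merge_sbel
from .grammar import (
    BELStatement,
    BELTerm,
    serialize_bel,
    strip_functions,
)
from .instances import AnnotatedSentence

__all__ = [
    "LEVELS",
    "Counts",
    "Scores",
    "EvalReport",
    "project",
    "score",
    "evaluate_statements",
    "measure_roundtrip_loss",
]

LEVELS = ("Term", "FS", "Function", "RS", "Relation", "State(REL)", "State(MRG)")

_BASE_RELATION = {
    "increases": "increases",
    "decreases": "decreases",
    "directlyIncreases": "increases",
    "directlyDecreases": "decreases",
}


@dataclass(frozen=True)
class Counts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "Counts") -> "Counts":
        return Counts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    def scores(self) -> "Scores":
        p = 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        r = 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        return Scores(p, r, f1)


@dataclass(frozen=True)
class Scores:
    """Precision, recall and their harmonic mean, as percentages."""

    p: float
    r: float
    f1: float


@dataclass(frozen=True)
class EvalReport:
    """Per-level counts and scores over the seven evaluation levels."""

    counts: Mapping[str, Counts]
    skipped: int = 0  # statements dropped for parse failures

    @property
    def scores(self) -> dict[str, Scores]:
        return {level: self.counts[level].scores() for level in LEVELS}

    def __getitem__(self, level: str) -> Scores:
        return self.counts[level].scores()

    def to_tsv(self) -> str:
        lines = ["level\tTP\tFP\tFN\tP\tR\tF1"]
        for level in LEVELS:
            c, s = self.counts[level], self.counts[level].scores()
            lines.append(
                f"{level}\t{c.tp}\t{c.fp}\t{c.fn}\t{s.p:.2f}\t{s.r:.2f}\t{s.f1:.2f}"
            )
        return "\n".join(lines) + "\n"

    def pretty(self) -> str:
        lines = [f"{'Evaluation levels':<12}  {'P (%)':>7} {'R (%)':>7} {'F1 (%)':>7}"]
        for level in LEVELS:
            s = self.counts[level].scores()
            lines.append(f"{level:<12}  {s.p:>7.2f} {s.r:>7.2f} {s.f1:>7.2f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Level projections


def _term_functions(term: BELTerm):
    """(function name, entity curie) pairs; a wrapping modifier governs every
    entity beneath it, a term-internal modifier only its own entity."""
    for mod in term.modifiers:
        for entity in term.entities:
            yield (mod.name, entity.curie)
    for entity in term.entities:
        for mod in entity.modifiers:
            yield (mod.name, entity.curie)


def _statement_pairs(stmt: BELStatement):
    """(subject curie, base relation, object curie) triples, recursing into a
    nested object (whose entities also pair with the outer subject)."""
    rel = _BASE_RELATION[stmt.relation]
    subj = [e.curie for e in stmt.subject.entities]
    if isinstance(stmt.object, BELStatement):
        inner = stmt.object
        obj = [e.curie for t in _terms(inner) for e in t.entities]
        yield from _statement_pairs(inner)
    else:
        obj = [e.curie for e in stmt.object.entities]
    for s in subj:
        for o in obj:
            yield (s, rel, o)


def _terms(stmt: BELStatement):
    yield stmt.subject
    if isinstance(stmt.object, BELStatement):
        yield from _terms(stmt.object)
    else:
        yield stmt.object


def project(statements: Iterable[BELStatement], level: str) -> frozenset:
    """Project one sentence's statements to the match units of a level."""
    statements = list(statements)
    if level == "Term":
        return frozenset(
            e.curie for s in statements for t in _terms(s) for e in t.entities
        )
    if level == "FS":
        return frozenset(
            f for s in statements for t in _terms(s) for f, _ in _term_functions(t)
        )
    if level == "Function":
        return frozenset(
            fe for s in statements for t in _terms(s) for fe in _term_functions(t)
        )
    if level == "RS":
        return frozenset(
            (s_, o) for stmt in statements for s_, _, o in _statement_pairs(stmt)
        )
    if level == "Relation":
        return frozenset(
            trip for stmt in statements for trip in _statement_pairs(stmt)
        )
    if level == "State(REL)":
        return frozenset(serialize_bel(strip_functions(s)) for s in statements)
    if level == "State(MRG)":
        return frozenset(serialize_bel(s) for s in statements)
    raise ValueError(f"unknown evaluation level {level!r}")


def score(
    gold: Mapping[str, frozenset], pred: Mapping[str, frozenset]
) -> tuple[Counts, Scores]:
    """Micro-averaged counts over per-sentence match-unit sets."""
    counts = Counts()
    for sid in set(gold) | set(pred):
        g = gold.get(sid, frozenset())
        p = pred.get(sid, frozenset())
        counts = counts + Counts(len(g & p), len(p - g), len(g - p))
    return counts, counts.scores()


def evaluate_statements(
    gold: Mapping[str, Sequence[BELStatement]],
    pred: Mapping[str, Sequence[BELStatement]],
    skipped: int = 0,
) -> EvalReport:
    """Score predicted against gold statements, per sentence, at all levels.

    At State(REL) the predictions are function-stripped but the gold
    statements are compared as written — the level quantifies how far
    relations alone get (functions carried by the gold statements count
    against it), which is why its scores collapse relative to Relation level.
    """
    counts = {}
    for level in LEVELS:
        gold_level = "State(MRG)" if level == "State(REL)" else level
        g = {sid: project(stmts, gold_level) for sid, stmts in gold.items()}
        p = {sid: project(stmts, level) for sid, stmts in pred.items()}
        counts[level], _ = score(g, p)
    return EvalReport(counts, skipped)


def measure_roundtrip_loss(corpus: Sequence[AnnotatedSentence]) -> EvalReport:
    """Convert a corpus to SBEL, merge back, and score against the originals.

    The deficit from 100% at each level is the information cost of the SBEL
    intermediate form on that corpus (nested relations and functions,
    self-relations, redundant multiple relations, modifier arguments).
    """
    gold = {s.sentence_id: list(s.statements) for s in corpus}
    qs = convert_corpus(corpus)
    by_sentence: dict[str, list] = {s.sentence_id: [] for s in corpus}
    for q in qs:
        by_sentence[q.sentence_id].append(q)
    pred = {sid: merge_sbel(group) for sid, group in by_sentence.items()}
    return evaluate_statements(gold, pred)
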