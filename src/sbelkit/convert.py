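"""BEL ↔ SBEL conversion.

SBEL (Simplified BEL) encodes a causal statement as a quintuple
``<func1, entity1, relation, func2, entity2>`` with at most one function per
side and only the two base relations ``increases``/``decreases``. Converting a
BEL statement applies, in order:

(i)   nested relations — keep only the inner statement, whose subject and
      object are plain terms;
(ii)  nested functions — keep the modifier closest to the entity, discard the
      outer ones;
(iii) ``complex()`` over k entities — distribute into k statements, each
      carrying ``complex`` as that side's function;
(iv)  self-relations (same entity on both sides) — discard;
(v)   multiple relations between one ordered entity pair in one sentence —
      keep only the first statement (corpus-level, see :func:`convert_corpus`);
(vi)  standard statements map one-to-one; ``directlyIncreases``/
      ``directlyDecreases`` canonicalize to the base relation.

Steps (i), (ii), (iv) and (v) lose information; merging SBEL statements back
to BEL (:func:`merge_sbel`) is lossless.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TYPE_CHECKING

from .grammar import (
    BELStatement,
    BELTerm,
    Entity,
    ModifierFunction,
    TERM_INTERNAL_MODIFIERS,
)

if TYPE_CHECKING:  # pragma: no cover
    from .instances import AnnotatedSentence

__all__ = [
    "SBELStatement",
    "SBEL_RELATIONS",
    "bel_to_sbel",
    "convert_corpus",
    "sbel_to_bel",
    "merge_sbel",
    "write_sbel_tsv",
    "read_sbel_tsv",
]

SBEL_RELATIONS = ("increases", "decreases")

_CANONICAL_RELATION = {
    "increases": "increases",
    "decreases": "decreases",
    "directlyIncreases": "increases",
    "directlyDecreases": "decreases",
}


@dataclass(frozen=True)
class SBELStatement:
    """The quintuple <func1, entity1, relation, func2, entity2>.

    ``func1``/``func2`` are modifier-function names (or None); entities are
    stored bare (term-internal modifier arguments have no slot here).
    """

    func1: str | None
    entity1: Entity
    relation: str
    func2: str | None
    entity2: Entity
    sentence_id: str | None = None
    source_bel_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.relation not in SBEL_RELATIONS:
            raise ValueError(f"SBEL relation must be one of {SBEL_RELATIONS}")
        if self.entity1.key == self.entity2.key:
            raise ValueError("self-relations cannot be encoded in SBEL")

    @property
    def pair_key(self) -> tuple[tuple[str, str], tuple[str, str]]:
        """Ordered (entity1, entity2) identity used by the first-statement
        deduplication rule; direction is part of the causal claim."""
        return (self.entity1.key, self.entity2.key)

    def quintuple(self) -> str:
        f1 = self.func1 or "None"
        f2 = self.func2 or "None"
        return (
            f"<{f1}, {self.entity1.curie}, {self.relation}, "
            f"{f2}, {self.entity2.curie}>"
        )


def _expand_side(term: BELTerm) -> list[tuple[str | None, Entity]]:
    """(function, entity) pairs for one side of a statement.

    Each entity receives the modifier closest to it: its own term-internal
    modifier if it has one, else the innermost wrapping modifier of the term
    (``complex`` when the term is a complex), else None.
    """
    wrapping = term.modifiers[-1].name if term.modifiers else None
    out = []
    for entity in term.entities:
        if entity.modifiers:
            func = entity.modifiers[0].name
        else:
            func = wrapping
        out.append((func, entity.bare()))
    return out


def bel_to_sbel(stmt: BELStatement) -> list[SBELStatement]:
    """Apply conversion rules (i)-(iv) and (vi) to one BEL statement.

    Returns zero or more quintuples; never raises on a valid statement.
    """
    inner = stmt.object if isinstance(stmt.object, BELStatement) else stmt
    assert isinstance(inner.object, BELTerm)
    relation = _CANONICAL_RELATION[inner.relation]
    out: list[SBELStatement] = []
    for func1, e1 in _expand_side(inner.subject):
        for func2, e2 in _expand_side(inner.object):
            if e1.key == e2.key:  # rule (iv)
                continue
            out.append(
                SBELStatement(
                    func1, e1, relation, func2, e2,
                    source_bel_id=stmt.statement_id,
                )
            )
    return out


def convert_corpus(sentences: Iterable["AnnotatedSentence"]) -> list[SBELStatement]:
    """Convert every statement of a corpus, applying rule (v).

    Within each sentence, each ordered (entity1, entity2) pair keeps only the
    quintuple from the earliest statement; output preserves corpus order. The
    result is in one-to-one correspondence with the labeled binary relation
    instances used for classifier training.
    """
    out: list[SBELStatement] = []
    for sentence in sentences:
        seen: set[tuple[tuple[str, str], tuple[str, str]]] = set()
        for stmt in sentence.statements:
            for q in bel_to_sbel(stmt):
                if q.pair_key in seen:
                    continue
                seen.add(q.pair_key)
                out.append(replace(q, sentence_id=sentence.sentence_id))
    return out


def _side_term(func: str | None, entities: Sequence[Entity]) -> BELTerm:
    """Rebuild a term from one quintuple side (or a merged entity list)."""
    if func is None:
        return BELTerm((), tuple(e.bare() for e in entities))
    if func == "complex" or len(entities) > 1:
        return BELTerm((ModifierFunction("complex"),), tuple(e.bare() for e in entities))
    entity = entities[0]
    if func in TERM_INTERNAL_MODIFIERS:
        return BELTerm(
            (), (Entity(entity.namespace, entity.identifier, entity.type_code,
                        (ModifierFunction(func),)),)
        )
    return BELTerm((ModifierFunction(func),), (entity.bare(),))


def sbel_to_bel(q: SBELStatement) -> BELStatement:
    """Rebuild the BEL statement ``func1(entity1) relation func2(entity2)``.

    A None function is omitted; term-internal modifier names (``pmod`` etc.)
    are re-attached inside the entity term so the output stays valid BEL.
    """
    return BELStatement(
        _side_term(q.func1, [q.entity1]),
        q.relation,
        _side_term(q.func2, [q.entity2]),
        statement_id=q.source_bel_id,
    )


def _dedup_keys(entities: Iterable[Entity]) -> list[Entity]:
    seen: set[tuple[str, str]] = set()
    out = []
    for e in entities:
        if e.key not in seen:
            seen.add(e.key)
            out.append(e)
    return out


def merge_sbel(qs: Sequence[SBELStatement]) -> list[BELStatement]:
    """Merge one sentence's quintuples back into BEL statements, losslessly.

    Subject merging: statements whose ``func1`` is ``complex`` and that agree
    on (relation, func2, entity2) pool their subject entities into one
    ``complex(...)`` term, in first-appearance order. Object merging is the
    symmetric step on ``func2``; it runs second, so a complex on both sides
    merges into a single statement when the grouped quintuples form the full
    Cartesian product. Everything else converts individually.
    """
    # record: [func1, [e1...], relation, func2, [e2...], source_id]
    records: list[list] = []
    subj_groups: dict[tuple, int] = {}
    for q in qs:
        if q.func1 == "complex":
            key = ("S", q.relation, q.func2, q.entity2.key)
            if key in subj_groups:
                records[subj_groups[key]][1].append(q.entity1)
                continue
            subj_groups[key] = len(records)
        records.append([q.func1, [q.entity1], q.relation, q.func2, [q.entity2],
                        q.source_bel_id])

    obj_groups: dict[tuple, int] = {}
    merged: list[list] = []
    for rec in records:
        func1, e1s, relation, func2, e2s, src = rec
        if func2 == "complex":
            key = ("O", func1, tuple(e.key for e in e1s), relation)
            if key in obj_groups:
                merged[obj_groups[key]][4].extend(e2s)
                continue
            obj_groups[key] = len(merged)
        merged.append(rec)

    out = []
    for func1, e1s, relation, func2, e2s, src in merged:
        out.append(
            BELStatement(
                _side_term(func1, _dedup_keys(e1s)),
                relation,
                _side_term(func2, _dedup_keys(e2s)),
                statement_id=src,
            )
        )
    return out


# ---------------------------------------------------------------------------
# 7-column TSV interchange

_TSV_HEADER = "sentence_id\tfunc1\tentity1\trelation\tfunc2\tentity2\tsource_bel_id"


def _entity_col(e: Entity) -> str:
    return f"{e.type_code}:{e.namespace}:{e.identifier}"


def _parse_entity_col(col: str) -> Entity:
    type_code, namespace, identifier = col.split(":", 2)
    return Entity(namespace, identifier, type_code)


def write_sbel_tsv(qs: Iterable[SBELStatement], handle: io.TextIOBase) -> None:
    handle.write(_TSV_HEADER + "\n")
    for q in qs:
        handle.write(
            "\t".join(
                [
                    q.sentence_id or "",
                    q.func1 or "None",
                    _entity_col(q.entity1),
                    q.relation,
                    q.func2 or "None",
                    _entity_col(q.entity2),
                    q.source_bel_id or "",
                ]
            )
            + "\n"
        )


def read_sbel_tsv(handle: io.TextIOBase) -> list[SBELStatement]:
    lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if lines and lines[0] == _TSV_HEADER:
        lines = lines[1:]
    out = []
    for ln in lines:
        sid, f1, e1, rel, f2, e2, src = ln.split("\t")
        out.append(
            SBELStatement(
                None if f1 == "None" else f1,
                _parse_entity_col(e1),
                rel,
                None if f2 == "None" else f2,
                _parse_entity_col(e2),
                sentence_id=sid or None,
                source_bel_id=src or None,
            )
        )
    return out
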