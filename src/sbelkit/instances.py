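"""Entity-mention alignment and RE/FD instance construction.

SBEL extraction decomposes into two sentence-level classification subtasks:

* RE (relation extraction): every ordered pair of aligned entities in a
  sentence is an instance, labeled ``increases``/``decreases``/``negative``;
* FD (function detection): every aligned entity is an instance, labeled with
  its modifier function (``act``, ``cat``, ..., ``complex``) or ``None``.

Entity identifiers are aligned to surface mentions by fuzzy matching
(normalized edit distance over token n-grams); instances mark the entities
with the @ / $ delimiters and replace their surfaces with typed placeholders.
Predicted relations and functions are reassembled into SBEL quintuples by
:func:`assemble_sbel`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .convert import SBELStatement
from .grammar import BELStatement, Entity

__all__ = [
    "AnnotatedSentence",
    "LabeledInstance",
    "MentionSpan",
    "InstanceConfig",
    "NEGATIVE_LABEL",
    "NO_FUNCTION_LABEL",
    "align_mentions",
    "build_re_instances",
    "build_fd_instances",
    "assemble_sbel",
    "write_instances_tsv",
    "read_instances_tsv",
]

logger = logging.getLogger(__name__)

NEGATIVE_LABEL = "negative"
NO_FUNCTION_LABEL = "None"

#: Placeholder tokens substituted for entity surfaces, by abundance type.
DEFAULT_PLACEHOLDERS: Mapping[str, str] = {
    "p": "GENE",
    "g": "GENE",
    "r": "GENE",
    "m": "GENE",
    "a": "CHEMICAL",
    "bp": "PROCESS",
    "path": "DISEASE",
}


@dataclass(frozen=True)
class AnnotatedSentence:
    """A corpus sentence with its gold entities and attached statements.

    ``gold_mentions`` optionally lists (entity curie, surface form) pairs for
    entities whose textual mention differs from the identifier (synonyms,
    appositions); alignment falls back to the identifier itself otherwise.
    """

    sentence_id: str
    text: str
    entities: tuple[Entity, ...]
    statements: tuple[BELStatement, ...] = ()
    gold_mentions: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class LabeledInstance:
    """A marked-text classification instance for RE or FD."""

    kind: str  # "RE" | "FD"
    marked_text: str
    label: str
    sentence_id: str
    entities: tuple[Entity, ...]  # (subject, object) for RE; (entity,) for FD

    def __post_init__(self) -> None:
        if self.kind not in ("RE", "FD"):
            raise ValueError("kind must be 'RE' or 'FD'")


@dataclass(frozen=True)
class MentionSpan:
    """A candidate mention: 0-based half-open character span + similarity."""

    start: int
    end: int
    text: str
    similarity: float


@dataclass(frozen=True)
class InstanceConfig:
    """Knobs for alignment and instance marking.

    similarity_threshold: minimum normalized edit-distance similarity
        (1 - dist / max(len)) for a span to count as a mention; 0.7 rejects
        accidental short matches (e.g. 'Ca' for Camk2a) while tolerating
        inflectional variants.
    max_ngram: longest token n-gram considered as a candidate mention.
    """

    similarity_threshold: float = 0.7
    max_ngram: int = 6
    subject_marker: str = "@"
    object_marker: str = "$"
    placeholders: Mapping[str, str] = field(default_factory=lambda: DEFAULT_PLACEHOLDERS)


_WORD = re.compile(r"[A-Za-z0-9]+")


def _align_target(
    text: str, target: str, threshold: float, max_ngram: int
) -> list[MentionSpan]:
    target = target.lower()
    tokens = [(m.start(), m.end()) for m in _WORD.finditer(text)]
    spans: list[MentionSpan] = []
    for i in range(len(tokens)):
        for j in range(i, min(i + max_ngram, len(tokens))):
            start, end = tokens[i][0], tokens[j][1]
            candidate = text[start:end]
            dist = edlib.align(candidate.lower(), target, task="distance")["editDistance"]
            sim = 1.0 - dist / max(len(candidate), len(target))
            if sim >= threshold:
                spans.append(MentionSpan(start, end, candidate, sim))
    spans.sort(key=lambda s: (-s.similarity, s.start, s.end - s.start))
    return spans


def align_mentions(
    text: str,
    entity: Entity,
    threshold: float = 0.7,
    max_ngram: int = 6,
) -> list[MentionSpan]:
    """Fuzzy-align an entity identifier to candidate mentions in a sentence.

    Candidates are token n-grams (alphanumeric tokens, n <= ``max_ngram``);
    each is scored by 1 - editdistance/max(len) against the identifier,
    case-insensitively. Spans below ``threshold`` are dropped; the best span
    comes first, ties broken by leftmost position. An empty result is an
    alignment failure and is logged.
    """
    spans = _align_target(text, entity.identifier, threshold, max_ngram)
    if not spans:
        logger.info(
            "alignment failure: %s not found in sentence %r...",
            entity.curie, text[:40],
        )
    return spans


def _alignments(
    sentence: AnnotatedSentence, config: InstanceConfig
) -> dict[tuple[str, str], list[MentionSpan]]:
    """Per-entity candidate spans, preferring gold surface forms if given."""
    out: dict[tuple[str, str], list[MentionSpan]] = {}
    for e in sentence.entities:
        forms = [f for curie, f in sentence.gold_mentions if curie == e.curie]
        spans: list[MentionSpan] = []
        for target in forms or [e.identifier]:
            spans.extend(
                _align_target(
                    sentence.text, target,
                    config.similarity_threshold, config.max_ngram,
                )
            )
        spans.sort(key=lambda s: (-s.similarity, s.start, s.end - s.start))
        if not spans:
            logger.info(
                "alignment failure: %s in sentence %s",
                e.curie, sentence.sentence_id,
            )
        out[e.key] = spans
    return out


def _mark(
    text: str,
    spans: Sequence[tuple[MentionSpan, str, str]],
) -> str:
    """Replace each span with 'marker placeholder marker', rightmost first."""
    out = text
    for span, marker, placeholder in sorted(spans, key=lambda t: -t[0].start):
        out = out[: span.start] + f"{marker} {placeholder} {marker}" + out[span.end :]
    return out


def _closest_pair(
    spans1: Sequence[MentionSpan], spans2: Sequence[MentionSpan]
) -> tuple[MentionSpan, MentionSpan] | None:
    """The non-overlapping mention pair with minimal character distance.

    When an entity has several mentions (e.g. an apposition), the closest
    pair is the training instance; overlapping spans cannot both be marked.
    """
    best = None
    for s1 in spans1:
        for s2 in spans2:
            if s1.end <= s2.start or s2.end <= s1.start:
                gap = abs(s1.start - s2.start)
                key = (gap, s1.start, s2.start)
                if best is None or key < best[0]:
                    best = (key, s1, s2)
    return None if best is None else (best[1], best[2])


def _placeholder(entity: Entity, config: InstanceConfig) -> str:
    return config.placeholders.get(entity.type_code, "ENTITY")


def build_re_instances(
    sentence: AnnotatedSentence,
    sbel: Sequence[SBELStatement],
    config: InstanceConfig | None = None,
) -> tuple[list[LabeledInstance], int]:
    """One RE instance per ordered pair of aligned entities.

    The first entity is wrapped in @, the second in $; surfaces are replaced
    by typed placeholders. The label comes from the sentence's SBEL
    statements, else ``negative``. Returns (instances, n_skipped_pairs);
    pairs with an unalignable entity are skipped and counted.
    """
    config = config or InstanceConfig()
    aligned = _alignments(sentence, config)
    labels = {q.pair_key: q.relation for q in sbel}
    instances: list[LabeledInstance] = []
    skipped = 0
    for e1 in sentence.entities:
        for e2 in sentence.entities:
            if e1.key == e2.key:
                continue
            pair = _closest_pair(aligned[e1.key], aligned[e2.key])
            if pair is None:
                skipped += 1
                continue
            s1, s2 = pair
            marked = _mark(
                sentence.text,
                [
                    (s1, config.subject_marker, _placeholder(e1, config)),
                    (s2, config.object_marker, _placeholder(e2, config)),
                ],
            )
            instances.append(
                LabeledInstance(
                    "RE",
                    marked,
                    labels.get((e1.key, e2.key), NEGATIVE_LABEL),
                    sentence.sentence_id,
                    (e1.bare(), e2.bare()),
                )
            )
    return instances, skipped


def first_functions(sbel: Sequence[SBELStatement]) -> dict[tuple[str, str], str]:
    """Each entity's first-occurring function across a sentence's quintuples.

    An entity appearing with different functions in several statements keeps
    the first one, so that one entity has exactly one function label.
    """
    out: dict[tuple[str, str], str] = {}
    for q in sbel:
        for entity, func in ((q.entity1, q.func1), (q.entity2, q.func2)):
            out.setdefault(entity.key, func or NO_FUNCTION_LABEL)
    return out


def build_fd_instances(
    sentence: AnnotatedSentence,
    sbel: Sequence[SBELStatement],
    config: InstanceConfig | None = None,
) -> tuple[list[LabeledInstance], int]:
    """One FD instance per aligned entity, marked with @ only.

    The label is the entity's first-occurring function across the sentence's
    SBEL statements, else ``None``. Returns (instances, n_skipped_entities).
    """
    config = config or InstanceConfig()
    aligned = _alignments(sentence, config)
    functions = first_functions(sbel)
    instances: list[LabeledInstance] = []
    skipped = 0
    for entity in sentence.entities:
        spans = aligned[entity.key]
        if not spans:
            skipped += 1
            continue
        marked = _mark(
            sentence.text,
            [(spans[0], config.subject_marker, _placeholder(entity, config))],
        )
        instances.append(
            LabeledInstance(
                "FD",
                marked,
                functions.get(entity.key, NO_FUNCTION_LABEL),
                sentence.sentence_id,
                (entity.bare(),),
            )
        )
    return instances, skipped


def assemble_sbel(
    re_predictions: Iterable[tuple[LabeledInstance, str]],
    fd_predictions: Iterable[tuple[LabeledInstance, str]],
) -> list[SBELStatement]:
    """Combine RE and FD predictions into SBEL quintuples.

    Each entity pair predicted ``increases``/``decreases`` yields one
    quintuple carrying the two entities' predicted functions; negative pairs
    yield nothing. A missing FD prediction is treated as None and logged.
    """
    functions: dict[tuple[str, tuple[str, str]], str | None] = {}
    for inst, label in fd_predictions:
        func = None if label == NO_FUNCTION_LABEL else label
        functions[(inst.sentence_id, inst.entities[0].key)] = func

    out: list[SBELStatement] = []
    for inst, label in re_predictions:
        if label not in ("increases", "decreases"):
            continue
        e1, e2 = inst.entities
        funcs = []
        for e in (e1, e2):
            key = (inst.sentence_id, e.key)
            if key not in functions:
                logger.info("missing FD prediction for %s; using None", e.curie)
            funcs.append(functions.get(key))
        out.append(
            SBELStatement(
                funcs[0], e1, label, funcs[1], e2, sentence_id=inst.sentence_id
            )
        )
    return out


# ---------------------------------------------------------------------------
# TSV interchange

_TSV_HEADER = "kind\tsentence_id\tmarked_text\tlabel\tentities"


def write_instances_tsv(
    instances: Iterable[LabeledInstance], handle
) -> None:
    handle.write(_TSV_HEADER + "\n")
    for inst in instances:
        ents = "|".join(
            f"{e.type_code}:{e.namespace}:{e.identifier}" for e in inst.entities
        )
        handle.write(
            "\t".join([inst.kind, inst.sentence_id, inst.marked_text, inst.label, ents])
            + "\n"
        )


def read_instances_tsv(handle) -> list[LabeledInstance]:
    lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if lines and lines[0] == _TSV_HEADER:
        lines = lines[1:]
    out = []
    for ln in lines:
        kind, sid, marked, label, ents = ln.split("\t")
        entities = []
        for col in ents.split("|"):
            type_code, ns, ident = col.split(":", 2)
            entities.append(Entity(ns, ident, type_code))
        out.append(LabeledInstance(kind, marked, label, sid, tuple(entities)))
    return out
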