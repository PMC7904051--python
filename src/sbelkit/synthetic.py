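"""Synthetic sentence/statement corpora and the worked-example fixture pack.

The generator emits template-based pseudo-English sentences whose gold BEL
statements cover the five complexity categories of real causal-statement
corpora — nested relations, nested functions, multi-entity ``complex()``
terms, self-relations and multiple relations between one pair — at
controllable fractions, the remainder being standard two-entity statements.
Entity mentions are embedded verbatim and each relation/function is cued by a
trigger word, so that oracle alignment succeeds and a lexical classifier has
learnable (optionally noised) signal. Everything is deterministic under the
configured seed.

The fixture pack (:data:`WORKED_STATEMENTS`, :func:`worked_sentences`)
collects the worked corpus statements used throughout the tests, keyed by
their corpus identifiers.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from .grammar import (
    BELStatement,
    BELTerm,
    Entity,
    ModifierFunction,
    parse_bel,
    serialize_bel,
)
from .instances import AnnotatedSentence

__all__ = [
    "GeneratorConfig",
    "GeneratedCorpus",
    "generate_corpus",
    "WORKED_STATEMENTS",
    "worked_examples",
    "worked_sentences",
    "corpus_to_json",
    "corpus_from_json",
    "corpus_to_tsv",
]

CATEGORIES = (
    "nested_relation",
    "nested_function",
    "multi_entity_complex",
    "self_relation",
    "multiple_relation",
)

_RELATION_TRIGGERS = {
    "increases": ("increased", "enhanced", "promoted", "stimulated", "induced"),
    "decreases": ("decreased", "reduced", "inhibited", "suppressed", "attenuated"),
}

_FUNCTION_PHRASES = {
    None: "",
    "act": "the activity of ",
    "cat": "the catalytic activity of ",
    "deg": "the degradation of ",
    "pmod": "the phosphorylation of ",
    "sec": "the secretion of ",
    "tloc": "the translocation of ",
    "kin": "the kinase activity of ",
    "complex": "the complex of ",
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for corpus generation.

    fractions: probability of each complexity category per sentence; the
        remaining mass yields standard statements. Defaults keep complex
        statements a minority, as in the corpora this emulates.
    function_distribution: weights over per-side functions for standard
        statement sides (``None`` = bare term); roughly one side in three
        carries a function, dominated by ``act``. ``complex`` only arises
        through the complex categories.
    relation_distribution: increases vs. decreases, ~73/27.
    trigger_noise: probability that a relation trigger word is replaced by
        one from the opposite class (makes the lexical signal imperfect).
    """

    n_sentences: int = 200
    fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "nested_relation": 0.05,
            "nested_function": 0.05,
            "multi_entity_complex": 0.07,
            "self_relation": 0.04,
            "multiple_relation": 0.05,
        }
    )
    function_distribution: Mapping[str | None, float] = field(
        default_factory=lambda: {
            None: 0.68,
            "act": 0.23,
            "pmod": 0.04,
            "cat": 0.02,
            "sec": 0.015,
            "deg": 0.01,
            "tloc": 0.005,
        }
    )
    relation_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"increases": 0.73, "decreases": 0.27}
    )
    entity_vocab_size: int = 300
    trigger_noise: float = 0.0
    distractor_rate: float = 0.3
    namespace: str = "SYN"
    seed: int = 0

    def validate(self) -> None:
        for name, frac in self.fractions.items():
            if name not in CATEGORIES:
                raise ValueError(f"unknown complexity category {name!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction for {name} outside [0, 1]")
        if sum(self.fractions.values()) > 1.0 + 1e-9:
            raise ValueError("category fractions sum to more than 1")
        for dist, what in (
            (self.function_distribution, "function"),
            (self.relation_distribution, "relation"),
        ):
            total = sum(dist.values())
            if total <= 0:
                raise ValueError(f"{what}_distribution has no positive mass")
        if self.n_sentences <= 0 or self.entity_vocab_size <= 0:
            raise ValueError("n_sentences and entity_vocab_size must be positive")


@dataclass(frozen=True)
class GeneratedCorpus(Sequence):
    """The generated sentences plus per-category planted counts."""

    sentences: tuple[AnnotatedSentence, ...]
    planted: Mapping[str, int]
    config: GeneratorConfig

    def __len__(self) -> int:
        return len(self.sentences)

    def __getitem__(self, i):
        return self.sentences[i]

    def __iter__(self) -> Iterator[AnnotatedSentence]:
        return iter(self.sentences)


def _weighted(rng: random.Random, dist: Mapping) -> object:
    items = list(dist.items())
    total = sum(w for _, w in items)
    x = rng.random() * total
    acc = 0.0
    for value, weight in items:
        acc += weight
        if x < acc:
            return value
    return items[-1][0]


class _SentenceFactory:
    def __init__(self, config: GeneratorConfig, rng: random.Random):
        self.config = config
        self.rng = rng
        # Fixed per-corpus vocabulary: identifier Ek with a stable type.
        self.vocab: list[Entity] = []
        for k in range(config.entity_vocab_size):
            type_code = _weighted(
                rng, {"p": 0.85, "a": 0.05, "r": 0.05, "bp": 0.05}
            )
            self.vocab.append(Entity(config.namespace, f"E{k + 1}", type_code))
        self.proteins = [e for e in self.vocab if e.type_code == "p"]
        if len(self.proteins) < 3:
            self.proteins = self.vocab  # degenerate tiny vocab

    # -- helpers -----------------------------------------------------------

    def _pick(self, n: int, proteins_only: bool = False) -> list[Entity]:
        pool = self.proteins if proteins_only else self.vocab
        return self.rng.sample(pool, n)

    def _relation(self) -> str:
        return _weighted(self.rng, self.config.relation_distribution)

    def _function(self) -> str | None:
        dist = {
            f: w
            for f, w in self.config.function_distribution.items()
            if f != "complex"
        }
        return _weighted(self.rng, dist)

    def _trigger(self, relation: str) -> str:
        if self.rng.random() < self.config.trigger_noise:
            relation = "decreases" if relation == "increases" else "increases"
        return self.rng.choice(_RELATION_TRIGGERS[relation])

    def _side(self, func: str | None, entity: Entity) -> BELTerm:
        if func is None:
            return BELTerm((), (entity,))
        if func == "pmod":
            return BELTerm(
                (),
                (Entity(entity.namespace, entity.identifier, entity.type_code,
                        (ModifierFunction("pmod"),)),),
            )
        return BELTerm((ModifierFunction(func),), (entity,))

    def _phrase(self, func: str | None, entity: Entity) -> str:
        return f"{_FUNCTION_PHRASES[func]}{entity.identifier}"

    # -- categories --------------------------------------------------------

    def standard(self):
        a, b = self._pick(2)
        f1, f2 = self._function(), self._function()
        rel = self._relation()
        stmt = BELStatement(self._side(f1, a), rel, self._side(f2, b))
        text = (
            f"In these cells, {self._phrase(f1, a)} markedly "
            f"{self._trigger(rel)} {self._phrase(f2, b)}."
        )
        return [stmt], text, [a, b]

    def nested_relation(self):
        a, b, c = self._pick(3)
        f1 = self.rng.choice(["act", "cat", None])
        f2 = self._function()
        rel_out, rel_in = self._relation(), self._relation()
        inner = BELStatement(self._side(f1, b), rel_in, self._side(f2, c))
        stmt = BELStatement(BELTerm((), (a,)), rel_out, inner)
        text = (
            f"Following stimulation by {a.identifier}, {self._phrase(f1, b)} "
            f"{self._trigger(rel_in)} {self._phrase(f2, c)}."
        )
        return [stmt], text, [a, b, c]

    def nested_function(self):
        rel = self._relation()
        if self.rng.random() < 0.5:
            a, b = self._pick(2, proteins_only=True)
            c = self.rng.choice([e for e in self.vocab if e.key not in (a.key, b.key)])
            outer = self.rng.choice(["cat", "act"])
            f2 = self._function()
            subject = BELTerm(
                (ModifierFunction(outer), ModifierFunction("complex")), (a, b)
            )
            stmt = BELStatement(subject, rel, self._side(f2, c))
            text = (
                f"{_FUNCTION_PHRASES[outer].capitalize()}the complex of "
                f"{a.identifier} and {b.identifier} {self._trigger(rel)} "
                f"{self._phrase(f2, c)}."
            )
            return [stmt], text, [a, b, c]
        a, b = self._pick(2)
        outer, inner = self.rng.choice([("act", "cat"), ("act", "deg"), ("cat", "sec")])
        f2 = self._function()
        subject = BELTerm((ModifierFunction(outer), ModifierFunction(inner)), (a,))
        stmt = BELStatement(subject, rel, self._side(f2, b))
        text = (
            f"{_FUNCTION_PHRASES[inner].capitalize()}{a.identifier} "
            f"{self._trigger(rel)} {self._phrase(f2, b)}."
        )
        return [stmt], text, [a, b]

    def multi_entity_complex(self):
        a, b = self._pick(2, proteins_only=True)
        c = self.rng.choice([e for e in self.vocab if e.key not in (a.key, b.key)])
        rel = self._relation()
        f2 = self._function()
        subject = BELTerm((ModifierFunction("complex"),), (a, b))
        stmt = BELStatement(subject, rel, self._side(f2, c))
        text = (
            f"The complex of {a.identifier} and {b.identifier} "
            f"{self._trigger(rel)} {self._phrase(f2, c)}."
        )
        return [stmt], text, [a, b, c]

    def self_relation(self):
        (a,) = self._pick(1, proteins_only=True)
        rel = self._relation()
        stmt = BELStatement(self._side("pmod", a), rel, self._side("deg", a))
        text = (
            f"The phosphorylation of {a.identifier} {self._trigger(rel)} "
            f"the degradation of {a.identifier}."
        )
        return [stmt], text, [a]

    def multiple_relation(self):
        a, b = self._pick(2)
        rel1 = self._relation()
        rel2 = "decreases" if rel1 == "increases" else "increases"
        f2a, f2b = "cat", "deg"
        stmt1 = BELStatement(BELTerm((), (a,)), rel1, self._side(f2a, b))
        stmt2 = BELStatement(BELTerm((), (a,)), rel2, self._side(f2b, b))
        text = (
            f"{a.identifier} {self._trigger(rel1)} {self._phrase(f2a, b)} "
            f"and also {self._trigger(rel2)} {self._phrase(f2b, b)}."
        )
        return [stmt1, stmt2], text, [a, b]


def generate_corpus(config: GeneratorConfig | None = None) -> GeneratedCorpus:
    """Generate a corpus of annotated sentences; deterministic given the seed.

    Every gold statement parses under the BEL grammar; per-category planted
    counts are returned on the result's ``planted`` mapping.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = random.Random(config.seed)
    factory = _SentenceFactory(config, rng)
    planted: Counter[str] = Counter()
    sentences: list[AnnotatedSentence] = []
    bel_seq = 1
    for i in range(config.n_sentences):
        x = rng.random()
        acc = 0.0
        category = "standard"
        for name in CATEGORIES:
            acc += config.fractions.get(name, 0.0)
            if x < acc:
                category = name
                break
        planted[category] += 1
        statements, text, entities = getattr(
            factory, category if category != "standard" else "standard"
        )()
        if rng.random() < config.distractor_rate:
            used = {e.key for e in entities}
            pool = [e for e in factory.vocab if e.key not in used]
            if pool:
                d = rng.choice(pool)
                text = text[:-1] + f", whereas {d.identifier} was unchanged."
                entities = entities + [d]
        with_ids = []
        for stmt in statements:
            with_ids.append(
                BELStatement(
                    stmt.subject, stmt.relation, stmt.object,
                    statement_id=f"BEL:9{bel_seq:06d}",
                )
            )
            bel_seq += 1
        sentences.append(
            AnnotatedSentence(
                sentence_id=f"SEN:9{i + 1:06d}",
                text=text,
                entities=tuple(entities),
                statements=tuple(with_ids),
            )
        )
    return GeneratedCorpus(tuple(sentences), dict(planted), config)


# ---------------------------------------------------------------------------
# Worked-example fixture pack

#: Worked corpus statements, keyed by their corpus identifiers ("FIG:1" for
#: the introductory example, which carries no identifier of its own).
WORKED_STATEMENTS: dict[str, str] = {
    "FIG:1": "complex(p(HGNC:ITGAV), p(HGNC:ITGB6)) increases p(HGNC:TGFB1)",
    "BEL:20073928": (
        'cat(complex(p(HGNC:ITGA2), p(HGNC:ITGB1))) increases '
        'bp(GOBP:"cell adhesion")'
    ),
    "BEL:20002944": (
        "p(HGNC:CTNNB1, pmod(p,S,37)) directlyIncreases deg(p(HGNC:CTNNB1))"
    ),
    "BEL:20045200": "p(HGNC:SUMO1) increases cat(p(HGNC:MDM2))",
    "BEL:20045202": "p(HGNC:SUMO1) decreases deg(p(HGNC:MDM2))",
    "BEL:200590504": (
        "p(MGI:Ins2) increases (act(p(MGI:Akt1)) increases p(MGI:Pde3b, pmod(p)))"
    ),
    "BEL:20037754": "p(MGI:Camk2a) increases act(p(MGI:Clcn3))",
    "BEL:20060574": "p(MGI:S100a13) increases sec(p(MGI:Il1a))",
    "BEL:20032282": "p(MGI:Pctp) decreases act(p(MGI:Soat1))",
    "BEL:20032284": "p(MGI:Pctp) increases act(p(MGI:Cyp7a1))",
    "BEL:20079246": "p(HGNC:BRAF, sub(V,600,E)) increases kin(p(HGNC:RPS6KA6))",
    "BEL:20054682": "p(MGI:Il1a) decreases r(MGI:Gja1)",
    "BEL:20054684": "p(MGI:Il1a) increases r(MGI:Gja6)",
    "BEL:20049348": "p(MGI:Cftr) decreases a(CHEBI:glutathione)",
    "BEL:200467681": 'p(MGI:Adam17) increases bp(GOBP:"inflammatory response")',
    "BEL:200313761": "p(MGI:Fcgr2b) decreases path(MESHD:Inflammation)",
}


def worked_examples() -> dict[str, BELStatement]:
    """The fixture statements parsed, with their identifiers attached."""
    out = {}
    for bel_id, text in WORKED_STATEMENTS.items():
        stmt = parse_bel(text)
        out[bel_id] = BELStatement(
            stmt.subject, stmt.relation, stmt.object, statement_id=bel_id
        )
    return out


def worked_sentences() -> dict[str, AnnotatedSentence]:
    """Corpus sentences with known text, for alignment fixtures.

    SEN:10003704 is the misalignment case ('Camk2a' has no faithful mention,
    only the spurious short match 'Ca'); SEN:10004988 is the apposition case
    (one entity mentioned twice, as a long form and its abbreviation).
    """
    ex = worked_examples()
    return {
        "SEN:10003704": AnnotatedSentence(
            "SEN:10003704",
            "ClC-3 is activated by Ca(2+)-calmodulin-dependent protein kinase "
            "II; however, the magnitude of the Ca(2+)-dependent Cl(-) current "
            "was unchanged in the Clcn3(-/-) animals.",
            (Entity("MGI", "Camk2a"), Entity("MGI", "Clcn3")),
            (ex["BEL:20037754"],),
        ),
        "SEN:10004988": AnnotatedSentence(
            "SEN:10004988",
            "In chow-fed Pctp-/- mice, acyl CoA:cholesterol acyltransferase "
            "(Acat) activity was markedly increased, "
            "3-hydroxy-3-methylglutaryl-CoA reductase activity was unchanged, "
            "and cholesterol 7alpha-hydroxylase activity was reduced.",
            (
                Entity("MGI", "Pctp"),
                Entity("MGI", "Soat1"),
                Entity("MGI", "Cyp7a1"),
            ),
            (ex["BEL:20032282"], ex["BEL:20032284"]),
            gold_mentions=(
                ("MGI:Soat1", "acyl CoA:cholesterol acyltransferase"),
                ("MGI:Soat1", "Acat"),
                ("MGI:Cyp7a1", "cholesterol 7alpha-hydroxylase"),
            ),
        ),
    }


# ---------------------------------------------------------------------------
# Corpus interchange (JSON mirror + TSV dialect)


def corpus_to_json(sentences: Sequence[AnnotatedSentence]) -> str:
    payload = {
        "sentences": [
            {
                "sentence_id": s.sentence_id,
                "text": s.text,
                "entities": [
                    f"{e.type_code}:{e.namespace}:{e.identifier}" for e in s.entities
                ],
                "gold_mentions": [list(pair) for pair in s.gold_mentions],
                "statements": [
                    {"id": st.statement_id, "bel": serialize_bel(st)}
                    for st in s.statements
                ],
            }
            for s in sentences
        ]
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def corpus_from_json(text: str) -> tuple[list[AnnotatedSentence], int]:
    """Load a corpus; returns (sentences, n_statement_parse_failures).

    Statements that fail to parse are skipped and counted, never fatal.
    """
    payload = json.loads(text)
    sentences: list[AnnotatedSentence] = []
    failures = 0
    for row in payload["sentences"]:
        entities = []
        for col in row["entities"]:
            type_code, ns, ident = col.split(":", 2)
            entities.append(Entity(ns, ident, type_code))
        statements = []
        for st in row["statements"]:
            try:
                stmt = parse_bel(st["bel"])
            except ValueError:
                failures += 1
                continue
            statements.append(
                BELStatement(
                    stmt.subject, stmt.relation, stmt.object,
                    statement_id=st.get("id"),
                )
            )
        sentences.append(
            AnnotatedSentence(
                row["sentence_id"],
                row["text"],
                tuple(entities),
                tuple(statements),
                tuple((c, f) for c, f in row.get("gold_mentions", [])),
            )
        )
    return sentences, failures


def corpus_to_tsv(sentences: Sequence[AnnotatedSentence]) -> str:
    """Line-oriented TSV dialect: SEN, ENT, MEN and BEL rows per sentence."""
    lines = []
    for s in sentences:
        lines.append(f"SEN\t{s.sentence_id}\t{s.text}")
        for e in s.entities:
            lines.append(f"ENT\t{s.sentence_id}\t{e.type_code}:{e.namespace}:{e.identifier}")
        for curie, form in s.gold_mentions:
            lines.append(f"MEN\t{s.sentence_id}\t{curie}\t{form}")
        for st in s.statements:
            lines.append(
                f"BEL\t{s.sentence_id}\t{st.statement_id or ''}\t{serialize_bel(st)}"
            )
    return "\n".join(lines) + "\n"
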