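"""Parsing, canonicalization and serialization of BEL statements.

The subset of the Biological Expression Language handled here is the one that
occurs in sentence-level causal-statement corpora: typed entity terms such as
``p(HGNC:TGFB1)`` or ``bp(GOBP:"cell adhesion")``, wrapping modifier functions
(``act``, ``cat``, ``deg``, ``sec``, ``tloc``, ``kin`` and the multi-argument
``complex``), term-internal modifiers (``pmod``, ``sub``, ...), the four causal
predicates, and at most one level of statement nesting, e.g.::

    p(MGI:Ins2) increases (act(p(MGI:Akt1)) increases p(MGI:Pde3b, pmod(p)))

Full OpenBEL 2.x (translocation arguments, reactions, lists) is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Union

__all__ = [
    "Entity",
    "ModifierFunction",
    "BELTerm",
    "BELStatement",
    "BELParseError",
    "RELATIONS",
    "TYPE_CODES",
    "WRAPPING_MODIFIERS",
    "TERM_INTERNAL_MODIFIERS",
    "parse_bel",
    "serialize_bel",
    "serialize_term",
    "list_entities",
    "canonicalize",
    "strip_functions",
]

#: Causal predicates accepted between subject and object.
RELATIONS = frozenset(
    {"increases", "decreases", "directlyIncreases", "directlyDecreases"}
)

#: Abundance designators: protein, abundance (chemical), RNA, gene, microRNA,
#: biological process, pathology.
TYPE_CODES = frozenset({"p", "a", "r", "g", "m", "bp", "path"})

#: Modifier functions that wrap a whole term, as in ``act(p(X))``.
#: ``cat`` is accepted as distinct from ``act``; corpora that fold catalysis
#: into activity can remap it downstream.
WRAPPING_MODIFIERS = frozenset({"act", "cat", "deg", "sec", "tloc", "kin", "complex"})

#: Modifiers written inside the entity term, as in ``p(X, pmod(p, S, 37))``.
TERM_INTERNAL_MODIFIERS = frozenset({"pmod", "sub", "trunc", "fus"})

_BARE_IDENTIFIER = re.compile(r"[A-Za-z0-9_.+-]+\Z")


class BELParseError(ValueError):
    """Raised when a BEL statement string cannot be parsed.

    ``offset`` is the 0-based character position where the problem was
    detected (half-open coordinates are used throughout the package).
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class ModifierFunction:
    """A modifier function name plus its raw argument string, if any.

    ``detail`` keeps arguments such as the ``p,S,37`` of
    ``pmod(p,S,37)`` verbatim (whitespace removed); it has no slot in the
    quintuple encoding and is ignored there, but is preserved for faithful
    BEL round-trips.
    """

    name: str
    detail: str | None = None


@dataclass(frozen=True)
class Entity:
    """A namespaced entity with its abundance type.

    ``modifiers`` holds term-internal modifier functions attached to this
    entity (e.g. a ``pmod``); wrapping modifiers live on the enclosing
    :class:`BELTerm`.
    """

    namespace: str
    identifier: str
    type_code: str = "p"
    modifiers: tuple[ModifierFunction, ...] = ()

    def __post_init__(self) -> None:
        if not self.namespace or not self.identifier:
            raise ValueError("namespace and identifier must be non-empty")
        if self.type_code not in TYPE_CODES:
            raise ValueError(f"unknown type code {self.type_code!r}")

    @property
    def key(self) -> tuple[str, str]:
        """Identity of the entity: (namespace, identifier)."""
        return (self.namespace, self.identifier)

    @property
    def curie(self) -> str:
        return f"{self.namespace}:{self.identifier}"

    def bare(self) -> "Entity":
        """The same entity without term-internal modifiers."""
        if not self.modifiers:
            return self
        return Entity(self.namespace, self.identifier, self.type_code)


@dataclass(frozen=True)
class BELTerm:
    """A (possibly modified) term: wrapping modifiers outer-to-inner plus
    one entity, or several entities when a ``complex`` modifier governs them."""

    modifiers: tuple[ModifierFunction, ...] = ()
    entities: tuple[Entity, ...] = ()

    def __post_init__(self) -> None:
        if not self.entities:
            raise ValueError("a term needs at least one entity")
        if len(self.entities) > 1 and "complex" not in {m.name for m in self.modifiers}:
            raise ValueError("multiple entities require a complex() modifier")


@dataclass(frozen=True)
class BELStatement:
    """Subject term, causal relation, and a term or one nested statement."""

    subject: BELTerm
    relation: str
    object: Union[BELTerm, "BELStatement"]
    statement_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if isinstance(self.object, BELStatement) and isinstance(
            self.object.object, BELStatement
        ):
            raise ValueError("statement nesting deeper than one level")


# ---------------------------------------------------------------------------
# Tokenizer


@dataclass(frozen=True)
class _Token:
    kind: str  # LPAR RPAR COMMA COLON IDENT QUOTED EOF
    text: str
    offset: int


_QUOTES_OPEN = '"“‘'
_QUOTES_CLOSE = {'"': '"', "“": "”", "‘": "’"}


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c == "(":
            tokens.append(_Token("LPAR", c, i))
            i += 1
        elif c == ")":
            tokens.append(_Token("RPAR", c, i))
            i += 1
        elif c == ",":
            tokens.append(_Token("COMMA", c, i))
            i += 1
        elif c == ":":
            tokens.append(_Token("COLON", c, i))
            i += 1
        elif c in _QUOTES_OPEN:
            close = _QUOTES_CLOSE[c]
            j = text.find(close, i + 1)
            if j < 0:
                raise BELParseError("unterminated quoted identifier", i)
            tokens.append(_Token("QUOTED", text[i + 1 : j], i))
            i = j + 1
        else:
            m = re.match(r"[^\s(),:\"“”‘’]+", text[i:])
            assert m is not None
            tokens.append(_Token("IDENT", m.group(0), i))
            i += len(m.group(0))
    tokens.append(_Token("EOF", "", n))
    return tokens


def _check_balance(text: str) -> None:
    depth = 0
    opens: list[int] = []
    in_quote: str | None = None
    for i, c in enumerate(text):
        if in_quote:
            if c == in_quote:
                in_quote = None
            continue
        if c in _QUOTES_OPEN:
            in_quote = _QUOTES_CLOSE[c]
        elif c == "(":
            depth += 1
            opens.append(i)
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise BELParseError("unbalanced parenthesis", i)
            opens.pop()
    if depth > 0:
        raise BELParseError("unbalanced parenthesis", opens[-1])


# ---------------------------------------------------------------------------
# Recursive-descent parser


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> _Token:
        return self.tokens[self.pos]

    def next(self) -> _Token:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, kind: str, what: str) -> _Token:
        tok = self.next()
        if tok.kind != kind:
            raise BELParseError(f"expected {what}", tok.offset)
        return tok

    def parse_statement(self, depth: int = 0) -> BELStatement:
        subject = self.parse_term()
        rel_tok = self.expect("IDENT", "a relation keyword")
        if rel_tok.text not in RELATIONS:
            raise BELParseError(
                f"unknown relation keyword {rel_tok.text!r}", rel_tok.offset
            )
        obj: BELTerm | BELStatement
        if self.peek().kind == "LPAR":
            if depth >= 1:
                raise BELParseError(
                    "unsupported structure: statement nesting deeper than one level",
                    self.peek().offset,
                )
            self.next()
            obj = self.parse_statement(depth + 1)
            self.expect("RPAR", "')' closing the nested statement")
        else:
            obj = self.parse_term()
        return BELStatement(subject, rel_tok.text, obj)

    def parse_term(self) -> BELTerm:
        head = self.expect("IDENT", "a function or type code")
        name = head.text
        if name in TYPE_CODES:
            self.expect("LPAR", "'('")
            entity = self.parse_entity(name)
            self.expect("RPAR", "')'")
            return BELTerm((), (entity,))
        if name == "complex":
            self.expect("LPAR", "'('")
            entities: list[Entity] = []
            while True:
                arg = self.parse_term()
                if arg.modifiers:
                    raise BELParseError(
                        "unsupported structure: modifier inside complex()",
                        self.peek().offset,
                    )
                entities.extend(arg.entities)
                if self.peek().kind == "COMMA":
                    self.next()
                    continue
                break
            self.expect("RPAR", "')' closing complex(...)")
            return BELTerm((ModifierFunction("complex"),), tuple(entities))
        if name in WRAPPING_MODIFIERS:
            self.expect("LPAR", "'('")
            inner = self.parse_term()
            self.expect("RPAR", f"')' closing {name}(...)")
            return BELTerm((ModifierFunction(name),) + inner.modifiers, inner.entities)
        raise BELParseError(f"unknown function or type code {name!r}", head.offset)

    def parse_entity(self, type_code: str) -> Entity:
        ns_tok = self.expect("IDENT", "a namespace")
        self.expect("COLON", "':' after the namespace")
        id_tok = self.next()
        if id_tok.kind not in ("IDENT", "QUOTED"):
            raise BELParseError("expected an entity identifier", id_tok.offset)
        mods: list[ModifierFunction] = []
        while self.peek().kind == "COMMA":
            self.next()
            mods.append(self.parse_internal_modifier())
        return Entity(ns_tok.text, id_tok.text, type_code, tuple(mods))

    def parse_internal_modifier(self) -> ModifierFunction:
        name_tok = self.expect("IDENT", "a term-internal modifier name")
        lpar = self.expect("LPAR", "'('")
        # Capture the raw argument text up to the matching ')', whitespace removed.
        depth = 1
        while True:
            tok = self.next()
            if tok.kind == "EOF":
                raise BELParseError("unbalanced parenthesis", tok.offset)
            if tok.kind == "LPAR":
                depth += 1
            elif tok.kind == "RPAR":
                depth -= 1
                if depth == 0:
                    break
        detail = re.sub(r"\s+", "", self.text[lpar.offset + 1 : tok.offset])
        return ModifierFunction(name_tok.text, detail or None)


def parse_bel(text: str) -> BELStatement:
    """Parse one BEL statement string into its tree.

    Whitespace and quote style are normalized: ``GOBP: "cell adhesion"`` and
    ``GOBP:"cell adhesion"`` yield the same :class:`Entity`.

    Raises
    ------
    BELParseError
        On unbalanced parentheses (naming the offset), unknown relation
        keywords, or statement nesting deeper than one level.
    """
    _check_balance(text)
    parser = _Parser(text)
    stmt = parser.parse_statement()
    tail = parser.peek()
    if tail.kind != "EOF":
        raise BELParseError("trailing input after the statement", tail.offset)
    return stmt


# ---------------------------------------------------------------------------
# Serialization


def _quote_if_needed(identifier: str) -> str:
    if _BARE_IDENTIFIER.match(identifier):
        return identifier
    return f'"{identifier}"'


def _serialize_entity(entity: Entity) -> str:
    inner = f"{entity.namespace}:{_quote_if_needed(entity.identifier)}"
    for mod in entity.modifiers:
        inner += f", {mod.name}({mod.detail or ''})"
    return f"{entity.type_code}({inner})"


def serialize_term(term: BELTerm) -> str:
    names = [m.name for m in term.modifiers]
    if "complex" in names:
        k = names.index("complex")
        if k != len(names) - 1:
            raise ValueError("complex() must be the innermost wrapping modifier")
        text = "complex(" + ", ".join(_serialize_entity(e) for e in term.entities) + ")"
        outer = term.modifiers[:k]
    else:
        text = _serialize_entity(term.entities[0])
        outer = term.modifiers
    for mod in reversed(outer):
        text = f"{mod.name}({text})"
    return text


def serialize_bel(stmt: BELStatement) -> str:
    """Canonical text of a statement: single spaces after commas, quotes only
    where the identifier requires them, modifiers nested innermost-last."""
    if isinstance(stmt.object, BELStatement):
        obj = f"({serialize_bel(stmt.object)})"
    else:
        obj = serialize_term(stmt.object)
    return f"{serialize_term(stmt.subject)} {stmt.relation} {obj}"


def canonicalize(text_or_stmt: str | BELStatement) -> str:
    """Canonical serialization of a statement given as text or tree."""
    stmt = parse_bel(text_or_stmt) if isinstance(text_or_stmt, str) else text_or_stmt
    return serialize_bel(stmt)


def _iter_terms(stmt: BELStatement) -> Iterator[BELTerm]:
    yield stmt.subject
    if isinstance(stmt.object, BELStatement):
        yield from _iter_terms(stmt.object)
    else:
        yield stmt.object


def list_entities(stmt: BELStatement) -> tuple[Entity, ...]:
    """All entity leaves in document order; duplicates preserved."""
    out: list[Entity] = []
    for term in _iter_terms(stmt):
        out.extend(term.entities)
    return tuple(out)


def _strip_term(term: BELTerm) -> BELTerm:
    # A bare multi-entity term is not serializable; keep the complex() shell.
    entities = tuple(e.bare() for e in term.entities)
    if len(entities) > 1:
        return BELTerm((ModifierFunction("complex"),), entities)
    return BELTerm((), entities)


def strip_functions(stmt: BELStatement) -> BELStatement:
    """The statement with every modifier function removed (a ``complex()``
    holding more than one entity is kept, as the entities need a container)."""
    obj: BELTerm | BELStatement
    if isinstance(stmt.object, BELStatement):
        obj = strip_functions(stmt.object)
    else:
        obj = _strip_term(stmt.object)
    return BELStatement(_strip_term(stmt.subject), stmt.relation, obj, stmt.statement_id)
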