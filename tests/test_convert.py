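"""BEL->SBEL conversion rules, corpus-level deduplication, and lossless merge."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from sbelkit import (
    AnnotatedSentence,
    Entity,
    SBELStatement,
    bel_to_sbel,
    convert_corpus,
    merge_sbel,
    parse_bel,
    sbel_to_bel,
    serialize_bel,
)
from sbelkit.convert import read_sbel_tsv, write_sbel_tsv


def quintuples(stmt):
    return [q.quintuple() for q in bel_to_sbel(stmt)]


class TestConversionRules:
    def test_complex_distributes_and_outer_function_dropped(self, worked):
        assert quintuples(worked["BEL:20073928"]) == [
            "<complex, HGNC:ITGA2, increases, None, GOBP:cell adhesion>",
            "<complex, HGNC:ITGB1, increases, None, GOBP:cell adhesion>",
        ]

    def test_self_relation_discarded(self, worked):
        assert bel_to_sbel(worked["BEL:20002944"]) == []

    def test_nested_relation_keeps_inner_statement(self, worked):
        assert quintuples(worked["BEL:200590504"]) == [
            "<act, MGI:Akt1, increases, pmod, MGI:Pde3b>"
        ]

    def test_directly_relations_canonicalize(self):
        stmt = parse_bel("p(X:A) directlyDecreases p(X:B)")
        (q,) = bel_to_sbel(stmt)
        assert q.relation == "decreases"

    def test_standard_statement_maps_one_to_one(self, worked):
        (q,) = bel_to_sbel(worked["BEL:20045200"])
        assert q.quintuple() == "<None, HGNC:SUMO1, increases, cat, HGNC:MDM2>"

    def test_never_two_functions_or_self_pairs(self, small_corpus):
        for sentence in small_corpus:
            for stmt in sentence.statements:
                for q in bel_to_sbel(stmt):
                    assert q.entity1.key != q.entity2.key
                    assert isinstance(q.func1, (str, type(None)))
                    assert isinstance(q.func2, (str, type(None)))

    def test_output_size_is_zero_or_product_of_arities(self, small_corpus):
        from sbelkit.grammar import BELStatement

        for sentence in small_corpus:
            for stmt in sentence.statements:
                inner = stmt.object if isinstance(stmt.object, BELStatement) else stmt
                subject_keys = {e.key for e in inner.subject.entities}
                object_keys = {e.key for e in inner.object.entities}
                expected = (
                    0
                    if subject_keys & object_keys
                    else len(subject_keys) * len(object_keys)
                )
                assert len(bel_to_sbel(stmt)) == expected


class TestCorpusDedup:
    def test_first_of_multiple_relations_survives(self, worked):
        sentence = AnnotatedSentence(
            "SEN:1", "irrelevant", (),
            (worked["BEL:20045200"], worked["BEL:20045202"]),
        )
        out = convert_corpus([sentence])
        assert [q.quintuple() for q in out] == [
            "<None, HGNC:SUMO1, increases, cat, HGNC:MDM2>"
        ]
        assert out[0].source_bel_id == "BEL:20045200"

    def test_no_duplicates_means_identity(self, worked):
        sentence = AnnotatedSentence(
            "SEN:1", "", (), (worked["BEL:20045200"], worked["FIG:1"])
        )
        out = convert_corpus([sentence])
        assert len(out) == 1 + 2

    def test_matches_brute_force_first_occurrence_scan(self, small_corpus):
        got = convert_corpus(small_corpus)
        # independent oracle: flatten all quintuples, then keep the earliest
        # per (sentence, ordered pair) by exhaustive scan
        expected = []
        for sentence in small_corpus:
            flat = [
                q
                for stmt in sentence.statements
                for q in bel_to_sbel(stmt)
            ]
            for i, q in enumerate(flat):
                earlier = any(
                    p.pair_key == q.pair_key for p in flat[:i]
                )
                if not earlier:
                    expected.append((sentence.sentence_id, q.quintuple()))
        assert [(q.sentence_id, q.quintuple()) for q in got] == expected

    def test_sbel_count_equals_distinct_pair_count(self, small_corpus):
        out = convert_corpus(small_corpus)
        pairs = {(q.sentence_id, q.pair_key) for q in out}
        assert len(pairs) == len(out)


class TestMerge:
    def test_subject_merge_reconstructs_complex_statement(self, worked):
        qs = bel_to_sbel(worked["BEL:20073928"])
        (merged,) = merge_sbel(qs)
        assert serialize_bel(merged) == (
            'complex(p(HGNC:ITGA2), p(HGNC:ITGB1)) increases '
            'bp(GOBP:"cell adhesion")'
        )

    def test_singleton_non_complex_is_direct_conversion(self, worked):
        (q,) = bel_to_sbel(worked["BEL:20045200"])
        assert merge_sbel([q]) == [sbel_to_bel(q)]

    def test_quintuple_to_bel_omits_none_function(self):
        q = SBELStatement(
            None, Entity("X", "A"), "increases", None, Entity("X", "B")
        )
        assert serialize_bel(sbel_to_bel(q)) == "p(X:A) increases p(X:B)"

    def test_complex_on_both_sides_matches_brute_force_grouping(self):
        stmt = parse_bel(
            "complex(p(X:A), p(X:B)) increases complex(p(X:C), p(X:D))"
        )
        qs = bel_to_sbel(stmt)
        assert len(qs) == 4
        got = frozenset(_shape(s) for s in merge_sbel(qs))
        # every merge order converges on the full product
        assert _oracle_fixpoints(qs) == {got} == {
            frozenset({
                ("complex", frozenset({("X", "A"), ("X", "B")}), "increases",
                 "complex", frozenset({("X", "C"), ("X", "D")})),
            })
        }

    @pytest.mark.parametrize("keep", [3, 2])
    def test_partial_products_merge_like_the_oracle_and_stay_lossless(self, keep):
        # a partial product admits several maximal merges depending on merge
        # order; the output must be one of the brute-force-reachable
        # fixpoints and must always be lossless
        stmt = parse_bel(
            "complex(p(X:A), p(X:B)) increases complex(p(X:C), p(X:D))"
        )
        for subset in itertools.combinations(bel_to_sbel(stmt), keep):
            merged = merge_sbel(list(subset))
            assert frozenset(_shape(s) for s in merged) in _oracle_fixpoints(
                list(subset)
            )
            # lossless: converting the merged statements reproduces the input
            back = [q for s in merged for q in bel_to_sbel(s)]
            assert set(back) == set(subset)

    def test_merge_is_left_inverse_on_lossless_class(self, small_corpus):
        from sbelkit.grammar import BELStatement, canonicalize

        checked = 0
        for sentence in small_corpus:
            for stmt in sentence.statements:
                if isinstance(stmt.object, BELStatement):
                    continue
                if len(stmt.subject.modifiers) > 1 or len(stmt.object.modifiers) > 1:
                    continue  # nested functions are lossy by design
                qs = bel_to_sbel(stmt)
                if not qs:
                    continue  # self-relations are lost by design
                if any(
                    m.detail for t in (stmt.subject, stmt.object)
                    for e in t.entities for m in e.modifiers
                ):
                    continue
                (rebuilt,) = merge_sbel(qs)
                assert serialize_bel(rebuilt) == canonicalize(stmt)
                checked += 1
        assert checked >= 40


def _shape(stmt):
    from sbelkit.grammar import BELStatement

    assert not isinstance(stmt.object, BELStatement)
    f1 = stmt.subject.modifiers[-1].name if stmt.subject.modifiers else (
        stmt.subject.entities[0].modifiers[0].name
        if stmt.subject.entities[0].modifiers else None
    )
    f2 = stmt.object.modifiers[-1].name if stmt.object.modifiers else (
        stmt.object.entities[0].modifiers[0].name
        if stmt.object.entities[0].modifiers else None
    )
    return (
        f1,
        frozenset(e.key for e in stmt.subject.entities),
        stmt.relation,
        f2,
        frozenset(e.key for e in stmt.object.entities),
    )


def _oracle_fixpoints(qs):
    """All maximal merge outcomes reachable by pairwise merging, brute force.

    Explores every order of applying a subject or object merge to any
    eligible pair of records until no pair can merge; returns the set of
    terminal states (as frozensets of statement shapes)."""

    def keys(es):
        return frozenset(e.key for e in es)

    def shape(rec):
        func1, e1s, rel, func2, e2s = rec
        return (func1, keys(e1s), rel, func2, keys(e2s))

    start = tuple(
        (q.func1, (q.entity1,), q.relation, q.func2, (q.entity2,)) for q in qs
    )
    terminals = set()

    def explore(recs):
        moves = []
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                if (
                    a[0] == b[0] == "complex"
                    and a[2] == b[2] and a[3] == b[3]
                    and keys(a[4]) == keys(b[4])
                ):
                    merged = (a[0], a[1] + b[1], a[2], a[3], a[4])
                    moves.append((i, j, merged))
                if (
                    a[3] == b[3] == "complex"
                    and a[2] == b[2] and a[0] == b[0]
                    and keys(a[1]) == keys(b[1])
                ):
                    merged = (a[0], a[1], a[2], a[3], a[4] + b[4])
                    moves.append((i, j, merged))
        if not moves:
            terminals.add(frozenset(shape(r) for r in recs))
            return
        for i, j, merged in moves:
            rest = tuple(r for k, r in enumerate(recs) if k not in (i, j))
            explore(rest + (merged,))

    explore(start)
    return terminals


# -- property: quintuple -> BEL -> quintuple identity ------------------------

entity_st = st.builds(
    Entity,
    namespace=st.just("X"),
    identifier=st.sampled_from("ABCDEFG"),
    type_code=st.sampled_from(["p", "a", "bp", "r"]),
)
func_st = st.sampled_from([None, "act", "cat", "deg", "pmod", "sec", "tloc"])


@settings(max_examples=200, derandomize=True)
@given(
    func1=func_st,
    e1=entity_st,
    relation=st.sampled_from(["increases", "decreases"]),
    func2=func_st,
    e2=entity_st,
)
def test_quintuple_bel_quintuple_identity(func1, e1, relation, func2, e2):
    if e1.key == e2.key:
        return
    q = SBELStatement(func1, e1, relation, func2, e2)
    assert bel_to_sbel(sbel_to_bel(q)) == [q]


def test_sbel_tsv_round_trip(small_corpus, tmp_path):
    qs = convert_corpus(small_corpus)
    path = tmp_path / "sbel.tsv"
    with open(path, "w") as fh:
        write_sbel_tsv(qs, fh)
    with open(path) as fh:
        back = read_sbel_tsv(fh)
    assert back == qs
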