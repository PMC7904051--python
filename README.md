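# sbelkit

Tooling for extracting causal statements from biomedical text via a
simplified intermediate representation of the Biological Expression
Language (BEL).

BEL expresses causal claims such as

```
complex(p(HGNC:ITGAV), p(HGNC:ITGB6)) increases p(HGNC:TGFB1)
```

— typed, namespaced entities (`p(...)` protein, `bp(...)` biological
process, ...), modifier functions (`act`, `cat`, `deg`, `pmod`, `sec`,
`tloc`, and the multi-argument `complex`), and causal predicates. Full BEL
statements can nest relations inside relations and functions inside
functions, which makes direct machine extraction hard. **SBEL** (Simplified
BEL) flattens each statement into quintuples

```
<func1, entity1, relation, func2, entity2>
```

with at most one function per side and only `increases`/`decreases` as
relations, so that extraction reduces to two sentence-level classification
subtasks: **RE** (relation extraction over ordered entity pairs) and **FD**
(function detection per entity). `sbelkit` implements:

- a BEL parser/serializer for the constructs found in sentence-level causal
  corpora (`sbelkit.grammar`);
- the six BEL→SBEL conversion rules (nested relations, nested functions,
  `complex()` distribution, self-relation and duplicate-relation removal,
  standard mapping) and the lossless SBEL→BEL merge (`sbelkit.convert`);
- fuzzy entity-mention alignment (normalized edit distance) and RE/FD
  instance construction with `@`/`$` entity markers, plus reassembly of
  predictions into quintuples (`sbelkit.instances`);
- a pluggable classifier contract with a deterministic lexical baseline and
  an optional transformer fine-tuning adapter (`sbelkit.models`);
- statement scoring at seven evaluation levels — Term, FS, Function, RS,
  Relation, State(REL), State(MRG) — with `P = TP/(TP+FP)`,
  `R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`, and round-trip conversion-loss
  measurement (`sbelkit.evaluate`);
- a synthetic corpus generator covering the five statement-complexity
  categories, plus a fixture pack of worked corpus statements
  (`sbelkit.synthetic`).

## Worked example

```python
>>> import sbelkit as sk
>>> stmt = sk.parse_bel(
...     'cat(complex(p(HGNC:ITGA2), p(HGNC:ITGB1))) increases bp(GOBP:"cell adhesion")')
>>> for q in sk.bel_to_sbel(stmt):
...     print(q.quintuple())
<complex, HGNC:ITGA2, increases, None, GOBP:cell adhesion>
<complex, HGNC:ITGB1, increases, None, GOBP:cell adhesion>
>>> print(sk.serialize_bel(sk.merge_sbel(sk.bel_to_sbel(stmt))[0]))
complex(p(HGNC:ITGA2), p(HGNC:ITGB1)) increases bp(GOBP:"cell adhesion")
```

The `complex()` is distributed over its two member proteins (each quintuple
carries `complex` as the subject function) and the outer `cat()` is dropped
— that drop is the conversion's information loss. Merging the two
quintuples back recovers everything the quintuples contain; the missing
`cat()` is charged to conversion, not to merging. Measuring that loss
corpus-wide:

```python
>>> corpus = sk.generate_corpus(sk.GeneratorConfig(n_sentences=600, seed=1))
>>> print(sk.measure_roundtrip_loss(list(corpus)).pretty())
Evaluation levels    P (%)   R (%)  F1 (%)
Term           100.00   96.29   98.11
FS             100.00   80.62   89.27
Function       100.00   80.20   89.02
RS             100.00   89.50   94.46
Relation       100.00   86.00   92.47
State(REL)      43.55   40.22   41.82
State(MRG)      89.85   82.99   86.28
```

Term-level loss comes only from discarded self-relations; Relation-level
recall additionally loses nested and duplicate relations; the State(REL)
row collapses because most statements carry entity functions that a
relations-only view cannot express; State(MRG), the full-statement view
after merging functions back in, retains an F1 in the mid-80s — the price
of the simplified representation.

A command-line layer mirrors the library:

```
sbel simulate --n 200 --seed 1 --out corpus.json
sbel convert corpus.json --out sbel.tsv
sbel merge sbel.tsv
sbel roundtrip corpus.json
sbel instances corpus.json --task re --out re.tsv
sbel train re.tsv --out re.model
sbel predict re.model re.tsv
```

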