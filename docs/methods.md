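# Methods

## The representation and its conversion

A BEL statement is `subject relation object`, where each side is a term —
one namespaced, typed entity (`p(HGNC:TGFB1)`, `bp(GOBP:"cell adhesion")`)
optionally wrapped in modifier functions (`act`, `cat`, `deg`, `sec`,
`tloc`, `kin`), optionally carrying term-internal modifiers (`pmod`, `sub`,
`trunc`, `fus`), with `complex(...)` the one function that governs several
entities — and the object may itself be a statement (one level of nesting
is accepted; deeper nesting does not occur in sentence-level causal corpora
and is rejected as unsupported). Relations are `increases`, `decreases` and
their `directly*` refinements.

SBEL flattens this to quintuples `<func1, entity1, relation, func2,
entity2>` with at most one function name per side and only the two base
relations. Conversion applies, in order:

1. **Nested relations** — keep only the inner statement (both of whose
   sides are plain terms); the outer claim is lost.
2. **Nested functions** — each entity keeps the modifier closest to it: its
   own term-internal modifier if present, else the innermost wrapping
   modifier of its term; outer modifiers are lost.
3. **`complex()` distribution** — a complex over k entities contributes k
   quintuple sides, each carrying `complex` as its function; a complex on
   both sides yields the Cartesian product of the two entity lists.
4. **Self-relations** — pairs with the same entity on both sides are
   dropped. The drop is applied per pair after complex distribution, so a
   partially overlapping complex loses only the colliding pairs; on
   non-overlapping sides the output size is exactly k1·k2.
5. **Multiple relations** — within one sentence, each *ordered* entity pair
   keeps only the quintuple from the earliest statement (direction is part
   of the causal claim, so (A,B) and (B,A) are distinct keys). This makes
   SBEL statements one-to-one with labeled binary relation instances.
6. **Standard statements** map one-to-one; `directlyIncreases/Decreases`
   canonicalize to the base relation.

Merging is the reverse, lossless step: each quintuple becomes
`func1(entity1) relation func2(entity2)` (a `None` function is omitted;
term-internal modifier names are re-attached inside the entity term so the
output stays valid BEL). Quintuples with a `complex` subject that agree on
(relation, func2, entity2) pool their subject entities into one
`complex(...)` in first-appearance order; the symmetric object merge runs
second, so a full two-sided product collapses to a single statement.
Partial products admit more than one maximal merge; the two-phase
subject-then-object order makes the outcome deterministic, and every
outcome is lossless (re-converting the merged statements reproduces the
input quintuples exactly — verified against a brute-force fixpoint
enumeration in the tests).

Quintuple function slots carry names only; `pmod(p,S,37)`-style arguments
are preserved by the parser (`ModifierFunction.detail`) but have no SBEL
slot and are genuinely lost in round-trip. The merge∘convert identity
therefore holds on the class of statements with no nesting, no
self-relation, at most one detail-free modifier per side.

## Round-trip loss measurement

Original statements are converted and merged back per sentence, and the
reconstruction is scored against the originals at seven levels, from entity
sets (Term) up to full canonical statement strings (State(MRG)). Counts are
micro-averaged with per-sentence grouping; matching is set-based after
canonical serialization. The secondary levels are operationalized as
relaxations: FS is the set of function types regardless of governed entity,
and RS is the (subject entity, object entity) pair ignoring relation type —
this guarantees FS ≥ Function and RS ≥ Relation. Relation-level triples use
the base relation (direction is what the level measures); the `directly*`
refinement still counts as loss at the two statement-string levels. A
wrapping modifier is credited to every entity beneath it at Function level;
nested gold statements contribute their inner triples plus the outer
subject paired with every inner entity. State(REL) compares
function-stripped predictions against gold statements *as written* — the
asymmetry is deliberate: it quantifies how far a relations-only extraction
gets against a gold standard whose statements carry functions, which is
exactly why its scores collapse relative to Relation level. Stripping keeps
a `complex()` shell when it holds more than one entity, since a bare
multi-entity term is not serializable BEL. Zero denominators (and TP = 0)
score 0 by convention.

## Extraction pipeline

Entity identifiers are aligned to sentence mentions by fuzzy matching:
candidate token n-grams (alphanumeric tokens, n ≤ 6) are scored by
normalized edit distance similarity `1 − d/max(len)` (case-insensitive,
via edlib) against the identifier — or against gold surface forms where the
corpus provides them — and spans under the 0.7 threshold are rejected. The
threshold trades recall for protection against short spurious matches: a
two-letter fragment of a long symbol scores ≈ 0.33 and is rejected, making
the failure an explicit alignment failure rather than a silent
misalignment. Both knobs are configurable (`InstanceConfig`).

RE builds one instance per ordered pair of aligned entities (n·(n−1) per
sentence), FD one per aligned entity (n). Entity surfaces are replaced by
type-code placeholders and wrapped in `@` (first/only entity) and `$`
(second); when an entity has several mentions (appositions), the
non-overlapping mention pair with minimal character distance is chosen. FD
labels follow the first-function rule: an entity appearing with different
functions across a sentence's quintuples keeps the first, so each entity
has exactly one function label. Assembly emits a quintuple for every pair
predicted `increases`/`decreases`, attaching each entity's predicted
function (missing FD predictions degrade to `None` and are logged).

With gold-label (oracle) classifiers, assembly reproduces the corpus
conversion output exactly whenever no entity carries conflicting functions
within a sentence — the first-function rule normalizes FD labels, and the
generator's study conditions (at most one function per entity per sentence)
satisfy this; on corpora with conflicts the identity holds up to that
normalization.

## Classifiers

The baseline is a multinomial logistic regression (scikit-learn, lbfgs,
C = `regularization`, default 1.0, `random_state` = seed) over unigram +
bigram counts of the marked text, eight trigger-lexicon count features, and
the absolute and signed token offset between the `@` and `$` markers. The
signed offset matters: the forward and reverse instances of a pair have
identical token bags, and only order-aware features separate a positive
pair from its reversed negative. Training and prediction are deterministic
under a fixed seed; single-class training data degrades to a constant
predictor with a warning. Negative RE instances are kept at natural
frequency (no sub-sampling), and no confidence-threshold filtering is
applied to FD predictions (a config hook exists, default off).

The transformer adapter is an optional contract only: it stores the
fine-tuning configuration (batch size 4, 3 epochs, max sequence length 100,
categorical cross-entropy, Adam at 1e-5, a pretrained biomedical encoder)
and consumes/produces the same LabeledInstance/label contract, but requires
`torch`/`transformers` at run time; everything else in the package is
independent of it, and all tests run with the baseline alone.

## Synthetic corpora

The generator emulates a sentence-aligned causal-statement corpus:
template-based pseudo-English with entity mentions embedded verbatim and
relation/function trigger words ("enhanced", "the degradation of", ...).
Per-sentence complexity categories are drawn at configurable fractions
(defaults: nested relations 5%, nested functions 5%, multi-entity complex
7%, self-relations 4%, multiple relations 5%, remainder standard — complex
constructs a minority, as in real corpora of this kind). Per-side functions
for standard statements are drawn with `None` at 0.68 and `act` dominating
the rest, and relations at 73/27 increases/decreases, mirroring the typical
skew of curated causal corpora. Entities are `SYN:E{k}` over a 300-symbol
vocabulary (85% proteins); a distractor entity participating in no
statement is added to 30% of sentences to provide natural negatives. A
`trigger_noise` knob flips relation triggers to the opposite class with the
given probability, bounding what a lexical classifier can achieve.

What the generator does *not* emulate: real mention variability (synonyms,
abbreviations, misalignable mentions), negation/knockout inversion,
coordination, long-distance dependencies, and annotation noise. Passing
tests therefore validate the representation machinery, the pipeline
decomposition and the scorer — not extraction performance on real text,
where those phenomena are the dominant error sources (alignment failures
additionally cascade into RE/FD). Known failure modes on real corpora
include misalignment of identifiers with no faithful surface form,
ambiguous function keywords ("release" as secretion vs. activity), and
apposition structures; the mention-pair and threshold rules above mitigate
but do not model them.

## Numerical and design choices

- Character offsets are 0-based half-open throughout.
- Canonical serialization: single spaces after commas, quotes only when an
  identifier needs them, modifiers nested innermost-last; both
  `NS:"multi word"` and `NS: "multi word"` parse identically.
- `cat` is parsed as a function distinct from `act`; corpora that fold
  catalysis into activity can remap downstream.
- When several inner statements could qualify under rule 1, the innermost,
  leftmost one is taken (with one nesting level the choice is unique).
- Alignment ties break leftmost; mention-pair ties break by (gap, leftmost
  subject, leftmost object).
- The acceptance script uses 600-sentence corpora for round-trip
  measurement and a 400/150 train/test split at 10% trigger noise for the
  baseline run — sizes at which the binomial spread of the planted
  fractions is a small fraction of the measured quantities while everything
  recomputes in seconds.

## Limitations

- The grammar covers the constructs attested in sentence-level causal
  corpora, not full OpenBEL 2.x (no translocation arguments, reactions, or
  list terms).
- Statement-level scoring is exact string matching after canonicalization;
  namespace near-misses are not credited.
- Whether corpus-style evaluations micro- or macro-average across sentences
  is not always documented; micro-averaging is used here throughout.
- Round-trip loss on a synthetic corpus depends on the planted category
  fractions; the defaults produce loss of the same order as curated
  corpora, but the numbers are properties of the generator's conditions,
  not of any external dataset.
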