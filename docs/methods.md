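# Methods

This note documents the models and procedures implemented in `silverner`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic experiments do and do not show.

## Data model

A corpus is a set of documents, each an ordered list of sentences; sentence
segmentation always comes from the input and is never recomputed, because
the sentence is the unit of alignment. An annotation is a character span
(0-based, half-open, Unicode code points) within one sentence, carrying a
semantic group (CHED, PRGE, DISO, SPE, or a registered extension), optional
opaque concept identifiers, and its source id. The token extent is derived:
the minimal token window whose tokens overlap the character extent. Deriving
rather than storing it means sub-token boundary variants (marking "tumour"
inside the printed "tumours") still map onto the same token window, which is
what lets cosine alignment resolve inflectional disagreements.

Two interchange formats are supported. The inline XML dialect is minimal by
design — `corpus / doc / s` structure with nested `e` elements — because an
inline format cannot express partial overlap and pretending otherwise
breaks round-trip guarantees; the standoff TSV carries anything. Writers
are canonical (fixed attribute order, sorted annotations, newline per
sentence) so that equal corpora produce byte-identical files; this makes
reproducibility checkable with `cmp`.

## Token weighting

The tokeniser lowercases and splits on maximal runs of non-alphanumeric
characters (underscore included), with no stemming or stopword list.
Inflection must survive tokenisation: "tumour" and "tumours" are genuinely
different annotator behaviours, and collapsing them would hide exactly the
disagreement the alignment is supposed to adjudicate. Stopwords need no
list because ubiquity itself drives their weight to zero.

IDF uses the textbook form `ln(N / df)` with df counted per document (not
per occurrence). A token present in every document weighs exactly 0; a
token unseen when the table was built gets `ln(N) + 1`, finite and strictly
above any observed weight, so query-time novelties are maximally
informative without producing infinities. Term frequency enters
multiplicatively (`tf · idf`); for 1–4-token entity spans tf is almost
always 1, but the rule keeps pathological repeated-token spans well
defined. Vectors are restricted to the tokens inside the annotation's own
extent; token order is honoured structurally — extents are contiguous, and
alignment additionally requires token-extent overlap — while the cosine
itself is order-free, as any cosine is.

## Harmonisation

For each sentence and group, all annotation pairs are scored; a pair aligns
when extents overlap in token space and the cosine is **strictly** greater
than τ (default 0.98). Strictness makes behaviour at a tie deterministic
and documented. The extent-overlap prerequisite prevents the one failure
mode cosine cannot see: two occurrences of the same term at different
positions in a sentence have identical vectors but are different mentions.

With K > 2 sources the pairwise rule needs an aggregation policy. The
implementation builds the full pairwise alignment graph and takes connected
components, which is symmetric in source order — a sequential
"each-contribution-against-the-next" scheme would make output depend on
input order. Components therefore admit chaining (a~b, b~c without a~c);
at τ = 0.98 chains are short in practice because near-identity is almost
transitive. Votes count **distinct sources** within a component, so a
source annotating twice cannot vote twice. The consensus annotation takes
the shortest member's boundaries (policy switchable to longest), with ties
broken by smaller start offset, then lexicographically smaller source id;
its concept ids are the order-stable union of the members'. All orderings
are total, so silver output is bit-reproducible and independent of the
order corpora are supplied in.

Groups are harmonised independently. A span tagged CHED by one source and
PRGE by another is *not* merged — tag polysemy is a real phenomenon the
method deliberately leaves unresolved, and merging across groups would
require a tag-arbitration rule the method does not define.

## Evaluation

Matching modes: exact (identical character extents), nested (containment in
either direction, equality included — the symmetric reading keeps
precision/recall symmetry when prediction and reference are swapped), and
cosine (token-extent overlap plus cosine strictly above τ; presets 0.98 and
0.9). True positives are counted by a maximum-cardinality one-to-one
matching per sentence and group, computed as an assignment problem with
per-edge weight `1000 + score` so cardinality strictly dominates and, among
maximum matchings, total cosine score breaks ties deterministically. The
one-to-one constraint is the standard fairness requirement: a single
prediction must not collect credit for several references. Precision,
recall and F use the zero conventions (P := 0 when tp+fp = 0, R := 0 when
tp+fn = 0, F := 0 when P+R = 0) so near-empty submissions score instead of
crashing; a group absent from the reference is flagged in the report. The
average row is the unweighted (macro) mean over groups. Document-subset
evaluation (`sample=(n, seed)`) draws without replacement from a seeded
generator and is fully deterministic.

Leniency is provable rather than empirical: every exact match is a nested
match and (identical extents giving identical vectors) a cosine match at
any τ, and lowering τ only adds edges; since adding edges never shrinks a
maximum matching, F(exact) ≤ F(nested) and F(exact) ≤ F(cos 0.98) ≤
F(cos 0.9) per group. The one theoretical exception — an annotation whose
tokens all weigh zero matches exactly but not by cosine — cannot produce an
exact pair unless both corpora annotate that weightless span identically.

## Synthetic corpora and annotator noise

Sentences are synthetic token sequences, not natural language: the
harmonisation mathematics sees only tokens, document frequencies and
extents, so linguistic realism would add nothing testable. Filler tokens
are drawn from a 2 000-word common vocabulary with 1/rank (Zipf-like)
weights, so the most frequent words approach document frequency N and
IDF 0 — giving boundary jitter its realistic harmless-absorption behaviour.
Entity mentions (1–4 tokens, per-group lexicons of 40 names) are planted
with at least two filler tokens between mentions, on average 2 per sentence
(Poisson). Defaults: 100 documents of 4–7 sentences — a desk-scale stand-in
for an abstract collection; the scale test uses 1 000 documents of 5–8
sentences. About 5 % of filler positions carry entity-lexicon words as
distractors, so spurious annotations can be textually plausible.

Annotator noise channels are independent Bernoulli/Poisson processes, the
simplest model producing every observed irregularity class: miss
(probability of dropping a true mention), spurious (Poisson rate per
sentence, placed on token windows clear of true mentions), boundary jitter
(extend or truncate by one token), tag confusion (ambiguous CHED/PRGE
mentions only), and inflectional stemming (mark only the stem of a surface
printed with its suffix). The random stream consumes exactly one draw per
decision point regardless of the rates, so changing one rate never perturbs
the other channels — this is what makes the "confusion harms only the
ambiguous groups" property exactly testable. Generation metadata the
simulator needs (alternate group, printed suffix) rides in prefixed opaque
concept ids (`alt:`, `infl:`) on truth annotations.

What passing synthetic tests shows: the consensus machinery filters
independent errors and repairs boundary noise as designed, with the
expected vote-threshold monotonicities. What it does not show: performance
on real biomedical text, where annotator errors are correlated (systems
sharing terminologies make the same mistakes), entity surface distributions
are heavy-tailed, and segmentation itself is noisy. Consensus gain shrinks
as error correlation grows; the simulator's independence assumption is the
optimistic end of that spectrum.

## Numerical choices and degenerate inputs

Cosines are clamped to 1.0 against floating-point overshoot. Zero-norm
vectors (spans of only weight-0 tokens) raise in the similarity primitive;
harmonisation catches this and treats the pair as non-alignable with
reported score 0, evaluation treats it as a non-match. An annotation
covering no token (punctuation-only span) is an error at vector-building
time. Empty corpora flow through every stage: zero annotations in, zero
out, zero scores under the conventions above. Vote thresholds above the
number of contributing sources, duplicate source ids, and text divergence
between supposedly shared corpora are hard errors that name the offender.

## Problem sizes

The test suite and acceptance script use 20–200-document corpora (the scale
check uses 1 000 × 4 sources) with 4–6 annotators; these sizes give stable
estimates for the properties asserted — counts in the hundreds to thousands
of mentions — while a full run stays in the tens of seconds on one CPU.

## Known limitations

* Alignment scores only annotation-internal tokens; no positional weighting
  or sentence context beyond the extent-overlap gate.
* Inline XML cannot express same-sentence partial overlap or discontinuous
  or cross-sentence mentions; the dialect forbids the latter entirely.
* Concept ids are carried and unioned, never resolved or arbitrated.
* Macro averaging weights small groups equally with large ones; there is no
  micro-average row.
* The vote filter is a hard threshold on distinct sources; no weighting of
  sources by reliability.
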