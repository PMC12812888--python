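# Methods

This note records the models and procedures `agrigraph` implements, the
parameters that matter, the deliberate design choices where the design was
open, and what the synthetic test corpus does and does not demonstrate.

## Text segmentation

Corpus rows sharing an `id` are concatenated in input order before
chunking, so all content of one record is segmented as a single unit
(`T_i = Concat(x_i1, …, x_im)`). Chunks are sliding token windows of size
S with overlap O (stride S − O). Two counts coexist deliberately:

* the closed-form count `⌊(T − O)/(S − O)⌋` (`nominal_chunk_count`),
  which drops a trailing remainder when (T − O) is not divisible by the
  stride;
* the chunker itself, which emits a final partial window so every token
  is covered — overlap-driven segmentation exists to prevent logical
  discontinuities, and silently discarding the document tail would defeat
  that purpose. The two agree exactly on divisible lengths, and the test
  suite asserts both behaviours.

"Token" is a pluggable contract; the default tokenizer is a
word/punctuation regex — deterministic, dependency-free, and swappable
for a model tokenizer. Defaults S = 1200, O = 200 suit model context
windows on real corpora; the test and acceptance runs use S = 40, O = 10
so that multi-chunk documents and boundary-straddling sentences actually
occur at toy scale.

Cleaning is an ordered regex rule table (full-width punctuation
normalization, whitespace collapse) applied before anything else; it is
idempotent, and blank rows are dropped with a logged count.

## Extraction and element summaries

A prompt per chunk asks the completion provider for entity and relation
records in a fixed delimiter grammar (`<|>` tuple, `##` record,
`<|COMPLETE|>` completion). The parser is tolerant: malformed records are
quarantined and counted, a missing completion delimiter is a truncation
error, and a relation whose endpoint is not among the chunk's entities is
quarantined rather than invented.

Entity linking is deterministic: case-fold, trim, collapse internal
whitespace, exact match. This is sufficient for templated and synthetic
data; fuzzy matching would be a configuration extension. Relation types
are an open set, canonicalized by lowercasing. The edge weight of a
merged relation is its occurrence frequency across chunks — the
deterministic component of evidence strength; semantic-similarity
weighting is not implemented because no formula for it is defined.

Each element's descriptions are concatenated in chunk order and truncated
to τ tokens (default 512, a conservative sub-budget of typical context
windows) before summarization. On provider failure the truncated
concatenation itself is kept as the summary, flagged as a fallback.

## Graph and communities

Entities are nodes; merged relations are undirected weighted edges
(parallel relations collapse with summed weight); isolated entities stay
as degree-0 nodes. Modularity is computed in the per-community aggregate
form, algebraically equal to the pairwise double sum
`(1/2m) Σ_ij [A_ij − k_i k_j/2m] δ(c_i, c_j)`; the test suite checks it
against a literal double-sum oracle to 1e−12. The all-in-one partition
scores exactly 0; degree-0 nodes contribute nothing.

Leaf communities come from the Leiden algorithm (`leidenalg`,
RB-configuration objective, resolution 1.0, fixed seed — both surfaced in
config for reproducibility), chosen for its guarantee that communities
are internally connected. The hierarchy is built by aggregate-graph
re-clustering: communities become nodes, inter-community weights are
summed, intra-community weight becomes a self-loop, and Leiden runs
again; iteration stops at one community, when coarsening stalls, or at
`max_levels` (default 2, matching the leaf/parent organization the
framework's reports use). Community ids are ordered by smallest member,
so identical inputs yield identical labels.

## Community reports

Leaf reports pack member chunks, element summaries, and the community's
internal entities and relations; when the packed context exceeds the
token budget, items are dropped chunk excerpts first, then entities by
ascending degree, then relations by ascending weight, keeping the
highest-evidence facts. Parent reports are generated from their
children's summary texts only — no chunks, no element summaries, no graph
structure reach the provider, which tests assert by inspecting recorded
provider calls. One report exists per community at every level, plus a
single root rollup over the top level so that global traversal has one
entry point.

## Index

Six artifacts persist as plain text (CSV tables with JSON-encoded list
cells; reports as JSON-lines) plus a manifest recording format version,
config hash, seed and counts. Referential integrity is checked before
writing and after reading, naming the first dangling id. Formats were
chosen for inspectability and byte-stable rewrites; `read(write(b)) == b`
holds exactly and is tested on every synthetic bundle.

Entity vectors are recomputed at query time from the stored embedding
text (entity name + element summary) rather than persisted: the encoders
are pure functions, so this is equivalent to precomputation while keeping
artifacts small and diff-able.

## Local querying

Matching is an exact cosine argmax over all entities — no approximate
nearest-neighbour index, since corpus scale here does not require one.
Ties break to the lexicographically smallest entity id. The evidence
table holds the one-hop subgraph (edges incident to the match, rendered
center-first because the graph is undirected; ordered by descending
weight), neighbour entities, the chunks mentioning the match, and the
summaries of the communities containing it (the root rollup is excluded:
it contains every entity and would defeat locality). A best similarity
below 0.2 — a package choice, not a calibrated value — attaches a
low-confidence warning instead of refusing to answer.

## Global querying

Traversal starts at the root rollup and proceeds breadth-first. Each
visited community's summary is scored 0–5; a community is kept iff
score ≥ θ. The printed keep rule in the source formulation uses a strict
inequality, but the accompanying threshold justification requires scores
3–5 to be kept at θ = 3, so ≥ is implemented; the boundary case is
pinned by a dedicated test. Descendants of a discarded community are
never scored. Partial answers come from kept communities with no kept
child (the finest kept evidence); each carries an evidence weight equal
to the sum of its community's member-relation weights. Conflict handling
is a deliberate simplification: fact statements are compared across
partials, and for predicates declared single-valued a disagreement on the
object is flagged, preferring the higher-evidence statement and leaving
ties unresolved for human review. Iterative re-retrieval and rewriting of
low-consistency fragments is out of scope. The reduce step sorts partials
by community id, making the final answer independent of generation order.

## Evaluation metrics

F1 is implemented as the harmonic mean `2PR/(P+R)`; zero denominators
raise an undefined-metric error rather than silently returning 0. BLEU-4
uses modified (reference-clipped) n-gram precisions with uniform weights,
the closest-length reference for r (ties to the shorter), brevity penalty
`exp(1 − r/c)` when c ≤ r, and no smoothing by default (an add-half
option exists behind config). Latency is the arithmetic mean of
per-question wall times.

## Synthetic corpus and stub providers

The generator emulates the type structure of real pest-and-disease
knowledge graphs: six entity types at roughly 35/25/20/10/10 proportions
(crops / diseases / pests / control measures / symptoms+pathogens), six
relation kinds with type-constrained slots ("disease infects crop",
"pest harms crop", "pathogen causes disease", …), triples realized as
templated declarative sentences, distractor sentences injected at a
configurable rate, and documents occasionally split across multiple CSV
rows to exercise grouping. Entity names are constructed so no name is a
token-suffix of another; combined with vocabulary validation in the stub
extraction rule, a sentence fragment cut at a chunk boundary can never
produce a spurious triple, while the overlapping neighbour chunk always
contains the intact sentence.

The stub completion provider is a rule table: extraction inverts the
sentence templates, summaries echo their packed context (making report
content exactly checkable), relevance scores are
`⌊5 · keyword-overlap(query, summary)⌋`, and answers embed their evidence
verbatim. The stub encoder hashes bag-of-words into a fixed number of
buckets and L2-normalizes.

What passing tests therefore show: the mechanics — segmentation
arithmetic, grammar-faithful parsing, merge/weight bookkeeping, graph and
community computation, index integrity, retrieval exactness, pruning
soundness, metric definitions, end-to-end determinism — are correct.
What they do not show: extraction quality on real prose, summary quality
from a real language model, or embedding quality of a trained encoder;
those depend on the providers plugged in behind the same contracts.

## Problem sizes

The default test corpus uses 20 entities, ~23 planted triples and 6–30
documents with S = 40, O = 10; acceptance runs use 30 documents and
exercise every entity as a local query and the five highest-degree
entities as hub/global queries. These sizes were chosen so that documents
span several chunks, hierarchies have at least two levels where the
community structure supports them, and the whole suite runs in seconds.

## Known limitations

* Entity linking is exact-match after normalization; paraphrase and
  cross-lingual variants of one entity stay separate nodes.
* Edge weights encode frequency only.
* The community hierarchy depth observed on toy graphs is often 1 (the
  leaf partition is already maximally coarse for aggregation), in which
  case the root rollup is the only higher level.
* Conflict resolution flags and prefers; it does not re-retrieve or
  rewrite.
* The CLI's offline providers require the synthetic truth file to wire
  the extraction stub; real-provider adapters are plugin points, not
  shipped.
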