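# agrigraph

Knowledge-graph retrieval-augmented question answering for crop pest and
disease corpora.

Agricultural practitioners looking for actionable knowledge about crop
diseases and insect pests face fragmented sources and keyword retrieval
that misses semantic relationships, while general-purpose language models
hallucinate in this terminology-heavy domain. `agrigraph` addresses this
by turning an unstructured corpus into a weighted entity knowledge graph
with a hierarchical community structure, and grounding every generated
answer in retrieved graph facts and cited community summaries.

The pipeline:

1. **Segmentation.** Rows of an `id,text` CSV are cleaned, grouped by id,
   tokenized, and cut into windows of *S* tokens (default 1200) with an
   overlap of *O* tokens (default 200) between neighbours, so facts that
   straddle a boundary survive in at least one window. The closed-form
   window count is `N = ⌊(T − O)/(S − O)⌋`; the chunker additionally emits
   a trailing partial window so the full text is always covered.
2. **Extraction.** A completion provider (pluggable; a deterministic
   offline stub is included) emits delimiter-structured entity and relation
   records per chunk over six entity types (Crops, Diseases, Insect pests,
   Symptoms, Control measures, Pathogen). Records merge across chunks
   under name normalization; relation multiplicity becomes the edge
   weight; each element's dispersed descriptions are truncated to τ tokens
   and condensed into one element summary.
3. **Graph & communities.** Entities are nodes of a weighted undirected
   graph G = (V, E, w). The Leiden algorithm partitions it (guaranteeing
   internally connected communities), quality measured by modularity
   `Q = (1/2m) Σ_ij [A_ij − k_i k_j / 2m] δ(c_i, c_j)`, and iterated
   coarsening builds a community hierarchy.
4. **Reports & index.** Every leaf community gets a report generated from
   its chunks, element summaries and internal graph structure; parent
   communities are summarized from their children's summaries only. Six
   artifacts persist to disk: entity table, relation table, raw units,
   text-chunk units, community metadata, community reports.
5. **Querying.** *Local*: the question is embedded, matched to the best
   entity by exact cosine argmax `e* = argmax_i cos(v_q, v_ei)`, and
   answered from a structured table of its one-hop subgraph plus the
   chunks and community summaries containing it. *Global*: community
   summaries are scored 0–5 for relevance top-down; a community is kept
   iff its score ≥ θ (default 3) and a discarded community's descendants
   are pruned unscored; kept communities produce partial answers that are
   conflict-checked and synthesized map-reduce style.
6. **Evaluation.** Precision `A_c/A_r`, recall `A_c/A_s`, F1
   `2PR/(P+R)`, unsmoothed BLEU-4 with brevity penalty
   `BP = exp(1 − r/c)` for `c ≤ r`, and mean per-question latency.

All model-dependent steps sit behind two provider contracts (completion,
embedding) with deterministic stubs, and a synthetic-corpus generator
plants a known toy knowledge graph into templated documents — so the whole
engine, through both query paths, is exactly testable offline.

## Worked example

```bash
agrigraph synth --out corpus.csv --truth truth.json --total-entities 16 --docs 8 --seed 5
# wrote corpus.csv (17 entities, 18 triples) and truth.json
printf 'chunk_size: 40\noverlap: 10\n' > config.yaml
agrigraph index --corpus corpus.csv --out index --truth truth.json --config config.yaml
```

The index step prints its stage counts — 13 CSV rows grouped into 8
documents, 8 chunks, and exactly the planted 17 entities and 18 relations
recovered with nothing quarantined; the 4 leaf communities score a
modularity of 0.513:

```json
{"documents": 8, "rows": 13, "chunks": 8, "entities": 17, "relations": 18,
 "quarantined": 0, "communities_per_level": [4],
 "modularity_per_level": [0.5132325141776938]}
```

A local query then retrieves the matching entity and answers from its
one-hop neighbourhood, citing the chunk and community it drew on:

```bash
agrigraph query-local --index index --question "which pests harm rice ?"
```

```json
{"entity": "rice", "similarity": 0.378,
 "answer": "Answer to: which pests harm rice ?\nCENTER ENTITY: rice (Crops)\n...\nRELATIONS:\n- (rice, harms, mauve aphid) [w=1]\n...",
 "citations": ["d3726a7323710623", "c0_3"]}
```

The answer embeds the evidence table: the planted pest `mauve aphid` is
the one-hop neighbour of `rice`, and the citations name the source chunk
and the community report that mention it. `agrigraph query-global` answers
synthesis questions the same way from the community hierarchy, printing
its score trace and any conflicts; `agrigraph evaluate` scores answer
files against references.

## Index layout

`index/` holds `documents.csv`, `chunks.csv`, `entities.csv`,
`relations.csv`, `communities.csv`, `community_reports.jsonl` and
`manifest.json` (format version, config hash, seed, counts, modularity per
level). All artifacts are plain text with stable ordering; re-indexing the
same corpus with the same config is byte-identical.

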